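"""Single-moderator meta-regressions with multiplicity control.

For each diel comparison, fits one model per environmental or trait
moderator (linear and quadratic variants for continuous ones; cell-means
coding for categorical ones), always alongside the diel exposure quotient
and the full random structure (reduced structure when the outcome metric
itself is the moderator). Benjamini-Yekutieli adjusts the omnibus QM
p-values within each comparison's model family.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dielmeta.meta import build_design, by_adjust, marginal_r2, qm_test, reml_fit
from dielmeta.moderators import build_model_set
from dielmeta.phylo import correlation_matrix, read_and_prune
from dielmeta.pipeline import DIEL_COMPARISONS, random_structure

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    effects = pd.read_csv(ROOT / "effects.csv")
    tree = read_and_prune((ROOT / "data" / "tree.nwk").read_text(),
                          sorted(set(effects["species"])))
    corr = correlation_matrix(tree, extend=True)

    rows = []
    for comp in DIEL_COMPARISONS:
        sub = effects.loc[effects["comparison"] == comp].reset_index(drop=True)
        specs, skipped = build_model_set(effects, comp)
        for entry in skipped:
            print(f"{comp}: {entry}")
        for ms in specs:
            data = sub.dropna(subset=[ms.moderator]).reset_index(drop=True)
            if len(data) < 12 or data[ms.moderator].nunique() < 2:
                continue
            try:
                X, names = build_design(data, ms.moderator, ms.kind, ms.quadratic)
                fit = reml_fit(data["yi"].to_numpy(), data["vi"].to_numpy(), X,
                               random_structure(data, corr, ms.random_preset),
                               coef_names=names)
                qm_idx = [i for i, nm in enumerate(names)
                          if nm not in ("intercept", "quotient")]
                q, dfq, pq = qm_test(fit, qm_idx)
                rows.append({"comparison": comp, "model": ms.label,
                             "moderator": ms.moderator, "kind": ms.kind,
                             "quadratic": ms.quadratic, "k": fit.k,
                             "QM": q, "QM_df": dfq, "QM_p": pq,
                             "r2_marginal": marginal_r2(fit)})
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as err:
                print(f"{ms.label}: FAILED ({err})")

    mods = pd.DataFrame(rows)
    mods["QM_p_adj"] = np.nan
    for comp in mods["comparison"].unique():
        m = mods["comparison"] == comp
        mods.loc[m, "QM_p_adj"] = by_adjust(mods.loc[m, "QM_p"].to_numpy())
    mods.to_csv(ROOT / "moderator_tests.csv", index=False)
    sig = mods.loc[mods["QM_p_adj"] < 0.05]
    print(f"fitted {len(mods)} moderator models; "
          f"{len(sig)} significant after Benjamini-Yekutieli adjustment")
    if len(sig):
        print(sig[["model", "QM_p", "QM_p_adj", "r2_marginal"]].to_string(index=False))


if __name__ == "__main__":
    main()
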