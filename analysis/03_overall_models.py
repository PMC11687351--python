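"""Overall phylogenetic multilevel meta-analysis per treatment comparison.

Fits the five-random-effect REML model (study, metric, phylogenetic and
non-phylogenetic species effects, observation) with the diel exposure
quotient as a fixed effect, then decomposes heterogeneity (multilevel
I^2), estimates phylogenetic signal (Pagel's lambda) on marginal
species-level predictions, and writes coefficient, variance-component and
species-prediction tables.
"""

from pathlib import Path

import pandas as pd

from dielmeta.meta import i2_multilevel, species_predictions
from dielmeta.phylo import correlation_matrix, pagels_lambda, read_and_prune
from dielmeta.pipeline import ALL_COMPARISONS, fit_overall

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    effects = pd.read_csv(ROOT / "effects.csv")
    tree = read_and_prune((ROOT / "data" / "tree.nwk").read_text(),
                          sorted(set(effects["species"])))
    corr = correlation_matrix(tree, extend=True)

    coef_rows, vc_rows, sig_rows = [], [], []
    for comp in ALL_COMPARISONS:
        sub = effects.loc[effects["comparison"] == comp].reset_index(drop=True)
        fit = fit_overall(sub, corr)
        total, per = i2_multilevel(fit)
        est, z = fit.coef["estimate"].iloc[0], fit.coef["zval"].iloc[0]
        print(f"{comp}: SMD {est:+.3f} (z = {z:.2f}, k = {fit.k}), "
              f"total I^2 = {100 * total:.0f}%")
        for _, r in fit.coef.iterrows():
            coef_rows.append({"comparison": comp, **r.to_dict()})
        for name, s2 in fit.sigma2.items():
            vc_rows.append({"comparison": comp, "component": name, "sigma2": s2,
                            "i2_share_pct": 100 * per[name]})
        preds = species_predictions(fit)
        sp = preds["species"].tolist()
        lam, lam_p = pagels_lambda(preds, corr.to_frame().loc[sp, sp])
        n_sig = int(preds["excludes_zero"].sum())
        print(f"  lambda = {lam:.3f} (p = {lam_p:.3f}); "
              f"{n_sig}/{len(preds)} species with CI excluding 0")
        sig_rows.append({"comparison": comp, "lambda": lam, "lambda_p": lam_p,
                         "n_species": len(preds), "n_species_ci_excl_zero": n_sig})
        if comp == "night_vs_day":
            preds.to_csv(ROOT / "species_predictions_night_vs_day.csv", index=False)

    pd.DataFrame(coef_rows).to_csv(ROOT / "overall_coefficients.csv", index=False)
    pd.DataFrame(vc_rows).to_csv(ROOT / "overall_variance_components.csv", index=False)
    pd.DataFrame(sig_rows).to_csv(ROOT / "phylogenetic_signal.csv", index=False)


if __name__ == "__main__":
    main()
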