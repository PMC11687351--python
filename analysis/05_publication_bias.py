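"""Publication-bias and sensitivity diagnostics.

Per diel comparison: funnel data (SMD vs its standard error), the
multilevel Egger regression (intercept test with SE as moderator inside
the full random structure) and the time-lag test (centred publication
year as moderator). Writes a diagnostics table, funnel CSVs and a funnel
figure.
"""

from pathlib import Path

import pandas as pd

from dielmeta.phylo import correlation_matrix, read_and_prune
from dielmeta.pipeline import DIEL_COMPARISONS, random_structure
from dielmeta.pubbias import egger_multilevel, funnel_data, time_lag_test

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    effects = pd.read_csv(ROOT / "effects.csv")
    tree = read_and_prune((ROOT / "data" / "tree.nwk").read_text(),
                          sorted(set(effects["species"])))
    corr = correlation_matrix(tree, extend=True)

    rows = []
    for comp in DIEL_COMPARISONS:
        sub = effects.loc[effects["comparison"] == comp].reset_index(drop=True)
        rnd = random_structure(sub, corr)
        e_b, e_z, e_p, _ = egger_multilevel(sub, rnd)
        t_b, t_z, t_p, _ = time_lag_test(sub, rnd)
        print(f"{comp}: Egger intercept z = {e_z:.2f} (p = {e_p:.3f}); "
              f"time-lag z = {t_z:.2f} (p = {t_p:.3f})")
        rows.append({"comparison": comp, "egger_intercept": e_b, "egger_z": e_z,
                     "egger_p": e_p, "year_slope": t_b, "year_z": t_z, "year_p": t_p})
        funnel_data(sub).to_csv(ROOT / f"funnel_{comp}.csv", index=False)
    pd.DataFrame(rows).to_csv(ROOT / "publication_bias.csv", index=False)

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fd = pd.read_csv(ROOT / "funnel_night_vs_day.csv")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(fd["yi"], fd["se"], s=12, alpha=0.5)
        ax.invert_yaxis()
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_xlabel("SMD (night vs. day)")
        ax.set_ylabel("standard error")
        fig.tight_layout()
        fig.savefig(ROOT / "funnel_night_vs_day.png", dpi=150)
        print("wrote funnel figure")
    except ImportError:
        print("matplotlib unavailable; skipped the funnel figure")


if __name__ == "__main__":
    main()
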