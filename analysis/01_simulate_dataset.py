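"""Generate the synthetic study set used by the downstream analyses.

Emulates the structure of the diel-pollination exclusion literature:
~120 studies on ~130 plant species, five pollination-benefit metrics
dominated by fruit set and seed set, binomial fruit-set counts, a
missing-SD mask on a few percent of arms, per-study geography/seasons,
plant traits and a dated phylogeny. Writes the four input files under
results/data/.
"""

from pathlib import Path

from dielmeta.simulate import SyntheticConfig, simulate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(n_studies=120, n_species=130, groups_per_study=3, seed=SEED)
    treatments, traits, env, newick = simulate_dataset(cfg)
    treatments.to_csv(OUT / "treatments.csv", index=False)
    traits.to_csv(OUT / "traits.csv", index=False)
    env.to_csv(OUT / "covariates.csv", index=False)
    (OUT / "tree.nwk").write_text(newick)
    n_groups = treatments.groupby(["study_id", "species", "metric"]).ngroups
    print(f"wrote {len(treatments)} treatment arms in {n_groups} experiment groups, "
          f"{traits.shape[0]} species trait records, {len(env)} study covariate rows")
    print(f"missing SDs to impute: {int(treatments['sd'].isna().sum() - (treatments['metric'] == 'fruit_set').sum())} "
          f"(plus {(treatments['metric'] == 'fruit_set').sum()} binomial fruit-set arms)")


if __name__ == "__main__":
    main()
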