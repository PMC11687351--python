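"""End-to-end orchestration: inputs -> effect sizes -> models -> diagnostics.

``run_pipeline`` is a pure function of (inputs, config, seed): stages run
in a fixed order, every stage logs row counts, and results are written as
tidy CSVs plus a JSON manifest. Inputs are either read from CSV/Newick
paths or generated by the synthetic-data module when the config has a
``simulate`` section.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import build_comparisons, binomial_sd, filter_outliers
from .environ import cbm_daylength, exposure_quotient, join_covariates, median_experiment_doy
from .impute import apply_sd_imputation, impute_exposure_hours, impute_study_year, mean_publication_lag
from .meta import (RandomEffect, build_design, by_adjust, i2_multilevel, marginal_means,
                   marginal_r2, qm_test, reml_fit, species_predictions)
from .moderators import build_model_set, recode_traits
from .phylo import correlation_matrix, pagels_lambda, read_and_prune, read_tree
from .pubbias import egger_multilevel, funnel_data, time_lag_test
from .simulate import SyntheticConfig, simulate_dataset

__all__ = ["run_pipeline", "prepare_treatments", "assemble_effects", "random_structure",
           "fit_overall"]

DIEL_COMPARISONS = ("night_vs_day", "day_vs_open", "night_vs_open")
ALL_COMPARISONS = DIEL_COMPARISONS + ("open_vs_closed",)


def prepare_treatments(treatments: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Missing-data stages: binomial SDs for fruit-set counts, regression
    imputation of remaining SDs, and study-year imputation."""
    df = treatments.copy()
    info = {}

    counts = df["sd"].isna() & df["n_flowers"].notna() & df["n_fruits"].notna()
    for idx in df.index[counts]:
        mean, sd = binomial_sd(int(df.loc[idx, "n_fruits"]), int(df.loc[idx, "n_flowers"]))
        df.loc[idx, ["mean", "sd", "n"]] = (mean, sd, int(df.loc[idx, "n_flowers"]))
    info["binomial_sd_rows"] = int(counts.sum())

    n_missing = int(df["sd"].isna().sum())
    if n_missing:
        df, report = apply_sd_imputation(df)
        info["sd_imputed_rows"] = n_missing
        info["sd_imputation_report"] = report
    else:
        info["sd_imputed_rows"] = 0

    if "pub_year" in df.columns and df["study_year"].isna().any():
        lag = mean_publication_lag(df["study_year"], df["pub_year"])
        miss = df["study_year"].isna()
        df.loc[miss, "study_year"] = [
            impute_study_year(int(py), lag) for py in df.loc[miss, "pub_year"]
        ]
        info["mean_publication_lag"] = lag
        info["year_imputed_rows"] = int(miss.sum())
    return df, info


def _study_environment(df: pd.DataFrame, p_coef: float) -> pd.DataFrame:
    studies = df.drop_duplicates("study_id").set_index("study_id")
    rows = []
    for sid, s in studies.iterrows():
        doy = median_experiment_doy(int(s["start_month"]), int(s["end_month"]),
                                    int(s["study_year"]))
        daylength = cbm_daylength(float(s["latitude"]), doy, p_coef)
        day_h, night_h = impute_exposure_hours(
            s.get("day_exposure_h"), s.get("night_exposure_h"), daylength)
        rows.append({"study_id": sid, "median_doy": doy, "daylength_h": daylength,
                     "day_hours": day_h, "night_hours": night_h})
    return pd.DataFrame(rows)


def assemble_effects(
    treatments: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    p_coef: float = 0.8333,
    outlier_threshold: float = 10.0,
):
    """Treatment arms -> filtered effect sizes with all moderators attached."""
    arm_cols = ["study_id", "species", "metric", "treatment", "n", "mean", "sd"]
    effects = build_comparisons(treatments[arm_cols])

    env = _study_environment(treatments, p_coef)
    env = join_covariates(env, covariates)
    effects = effects.merge(env, on="study_id", how="left")
    effects["exposure_quotient"] = [
        exposure_quotient(c, d, n)
        for c, d, n in zip(effects["comparison"], effects["day_hours"], effects["night_hours"])
    ]
    meta_cols = [c for c in ("pub_year", "study_year", "latitude") if c in treatments.columns]
    if meta_cols:
        effects = effects.merge(
            treatments.drop_duplicates("study_id")[["study_id"] + meta_cols],
            on="study_id", how="left")
    if traits is not None:
        effects = effects.merge(traits, on="species", how="left")

    # pollination dependency (open vs closed SMD) as a species-level moderator
    dep = (effects.loc[effects["comparison"] == "open_vs_closed"]
           .groupby("species")["yi"].mean().rename("dependency_smd"))
    effects = effects.merge(dep, on="species", how="left")

    kept, removed = filter_outliers(effects, outlier_threshold)
    kept = kept.reset_index(drop=True)
    kept["obs_id"] = [f"obs{i:05d}" for i in range(len(kept))]
    return kept, removed, env


def random_structure(effects: pd.DataFrame, corr, preset: str = "full") -> list[RandomEffect]:
    """The five-component random structure (study, metric, phylogenetic and
    non-phylogenetic species, observation); the ``reduced`` preset drops
    the metric term (used when metric itself is the moderator)."""
    comps = [RandomEffect("study", effects["study_id"].to_numpy())]
    if preset == "full":
        comps.append(RandomEffect("metric", effects["metric"].to_numpy()))
    elif preset != "reduced":
        raise ValueError(f"unknown random preset {preset!r}")
    comps += [
        RandomEffect("species_phylo", effects["species"].to_numpy(),
                     corr.to_frame() if hasattr(corr, "to_frame") else corr),
        RandomEffect("species_nonphylo", effects["species"].to_numpy()),
        RandomEffect("obs", effects["obs_id"].to_numpy()),
    ]
    return comps


def fit_overall(effects: pd.DataFrame, corr, preset: str = "full"):
    """Overall (intercept + exposure quotient) multilevel model for one
    comparison's effect sizes."""
    quot = effects["exposure_quotient"].to_numpy(dtype=float)
    if np.ptp(quot) == 0:
        X, names = np.ones((len(effects), 1)), ["intercept"]
    else:
        X, names = build_design(effects, kind="none")
    return reml_fit(effects["yi"].to_numpy(), effects["vi"].to_numpy(), X,
                    random_structure(effects, corr, preset), coef_names=names)


def _tree_for_species(tree_text: str, species: set) -> object:
    tree = read_tree(tree_text)
    return read_and_prune(tree, sorted(species))


def run_pipeline(config: dict | str, outdir: str | Path) -> dict:
    """Run every stage in order and write tidy outputs plus a manifest."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = []

    def stage(name, rows_in=None, rows_out=None, **kw):
        log.append({"stage": name, "rows_in": rows_in, "rows_out": rows_out, **kw})

    seed = int(config.get("seed", 0))
    if "simulate" in config:
        cfg = SyntheticConfig(**{**config["simulate"], "seed": seed})
        treatments, traits, env_cov, tree_text = simulate_dataset(cfg)
        stage("simulate", rows_out=len(treatments))
    else:
        inp = config["inputs"]
        treatments = pd.read_csv(inp["treatments"])
        traits = pd.read_csv(inp["traits"]) if inp.get("traits") else None
        env_cov = pd.read_csv(inp["covariates"]) if inp.get("covariates") else None
        tree_text = Path(inp["tree"]).read_text()
        stage("load", rows_out=len(treatments))

    if traits is not None:
        n0 = len(traits)
        traits, recode_log = recode_traits(traits)
        stage("recode_traits", rows_in=n0, rows_out=len(traits), log=recode_log)
        treatments = treatments.loc[treatments["species"].isin(traits["species"])]

    n0 = len(treatments)
    treatments, prep_info = prepare_treatments(treatments)
    stage("prepare", rows_in=n0, rows_out=len(treatments),
          binomial_sd_rows=prep_info["binomial_sd_rows"],
          sd_imputed_rows=prep_info["sd_imputed_rows"])

    effects, removed, env = assemble_effects(
        treatments, traits, env_cov,
        p_coef=float(config.get("p_coef", 0.8333)),
        outlier_threshold=float(config.get("outlier_threshold", 10.0)),
    )
    stage("effect_sizes", rows_in=len(treatments), rows_out=len(effects),
          outliers_removed=len(removed))
    effects.to_csv(outdir / "effects.csv", index=False)
    removed.to_csv(outdir / "effects_removed.csv", index=False)

    tree = _tree_for_species(tree_text, set(effects["species"]))
    corr = correlation_matrix(tree, extend=True)

    results = {"config": config, "n_effects": len(effects),
               "n_outliers_removed": len(removed),
               "counts": effects["comparison"].value_counts().to_dict()}
    coef_rows, vc_rows, het_rows, bias_rows, mod_rows = [], [], [], [], []
    for comp in ALL_COMPARISONS:
        sub = effects.loc[effects["comparison"] == comp].reset_index(drop=True)
        if len(sub) < 10:
            stage(f"overall:{comp}", rows_in=len(sub), status="SKIPPED: too few effects")
            continue
        fit = fit_overall(sub, corr)
        total, per = i2_multilevel(fit)
        for _, r in fit.coef.iterrows():
            coef_rows.append({"model": f"overall:{comp}", **r.to_dict()})
        for name, s2 in fit.sigma2.items():
            vc_rows.append({"model": f"overall:{comp}", "component": name, "sigma2": s2,
                            "i2_share": per[name]})
        het_rows.append({"model": f"overall:{comp}", "i2_total": total,
                         "QE": fit.QE[0], "QE_df": fit.QE[1], "QE_p": fit.QE[2],
                         "loglik": fit.loglik, "k": fit.k})
        results[f"overall_{comp}"] = {
            "estimate": float(fit.coef["estimate"].iloc[0]),
            "zval": float(fit.coef["zval"].iloc[0]),
            "i2_total": total, "i2_per_component": per, "k": fit.k,
        }
        stage(f"overall:{comp}", rows_in=len(sub), rows_out=fit.k)

        preds = species_predictions(fit)
        preds.insert(0, "comparison", comp)
        sp = preds["species"].tolist()
        lam, lam_p = pagels_lambda(preds, corr.to_frame().loc[sp, sp])
        results[f"lambda_{comp}"] = {"lambda": lam, "p": lam_p}
        results[f"species_sig_{comp}"] = int(preds["excludes_zero"].sum())
        if comp == "night_vs_day":
            preds.to_csv(outdir / "species_predictions.csv", index=False)

        if comp in DIEL_COMPARISONS:
            # publication-bias diagnostics with the full random structure
            rnd = random_structure(sub, corr)
            e_int, e_z, e_p, _ = egger_multilevel(sub, rnd)
            t_b, t_z, t_p, _ = time_lag_test(sub, rnd)
            bias_rows.append({"comparison": comp, "egger_intercept": e_int, "egger_z": e_z,
                              "egger_p": e_p, "year_slope": t_b, "year_z": t_z, "year_p": t_p})
            results[f"bias_{comp}"] = bias_rows[-1]

            mod_cfg = config.get("moderators", {})
            specs, skip_log = build_model_set(
                effects, comp,
                continuous=mod_cfg.get("continuous"),
                categorical=mod_cfg.get("categorical"))
            stage(f"moderators:{comp}", rows_out=len(specs), skipped=skip_log)
            for ms in specs:
                rows = sub.dropna(subset=[ms.moderator]).reset_index(drop=True)
                if len(rows) < 12 or rows[ms.moderator].nunique() < 2:
                    continue
                try:
                    X, names = build_design(rows, ms.moderator, ms.kind, ms.quadratic)
                    fit_m = reml_fit(rows["yi"].to_numpy(), rows["vi"].to_numpy(), X,
                                     random_structure(rows, corr, ms.random_preset),
                                     coef_names=names)
                    qm_idx = [i for i, nm in enumerate(names)
                              if nm not in ("intercept", "quotient")]
                    q, dfq, pq = qm_test(fit_m, qm_idx)
                    mod_rows.append({"comparison": comp, "model": ms.label,
                                     "moderator": ms.moderator, "kind": ms.kind,
                                     "quadratic": ms.quadratic, "k": fit_m.k,
                                     "QM": q, "QM_df": dfq, "QM_p": pq,
                                     "r2_marginal": marginal_r2(fit_m)})
                except (ValueError, RuntimeError, np.linalg.LinAlgError) as err:
                    stage(f"moderator:{ms.label}", status=f"FAILED: {err}")

    mods = pd.DataFrame(mod_rows)
    if not mods.empty:
        # BY adjustment across the moderator family, once per comparison type
        mods["QM_p_adj"] = np.nan
        for comp in mods["comparison"].unique():
            m = mods["comparison"] == comp
            mods.loc[m, "QM_p_adj"] = by_adjust(mods.loc[m, "QM_p"].to_numpy())
        mods.to_csv(outdir / "moderator_tests.csv", index=False)
    pd.DataFrame(coef_rows).to_csv(outdir / "coefficients.csv", index=False)
    pd.DataFrame(vc_rows).to_csv(outdir / "variance_components.csv", index=False)
    pd.DataFrame(het_rows).to_csv(outdir / "heterogeneity.csv", index=False)
    if bias_rows:
        pd.DataFrame(bias_rows).to_csv(outdir / "publication_bias.csv", index=False)
    funnel_data(effects.loc[effects["comparison"] == "night_vs_day"]).to_csv(
        outdir / "funnel_night_vs_day.csv", index=False)
    tree.write(path=str(outdir / "pruned_tree.nwk"), schema="newick",
               unquoted_underscores=True)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "stages": log,
        "counts": results["counts"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    results["moderator_tests"] = mods
    return results
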