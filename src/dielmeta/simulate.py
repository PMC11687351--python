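"""Synthetic diel-pollination datasets with known ground truth.

Two levels of generator are provided:

``simulate_effects``
    draws effect sizes directly from the five-component multilevel model
    (yi ~ N(X beta + Z u, vi)), the sharp tool for parameter-recovery and
    calibration experiments;

``simulate_dataset``
    emits the full input schema the pipeline reads — treatment-level
    arms (Gaussian outcomes, plus binomial fruit-set counts), a trait
    table, per-study environments and a dated tree — so every stage from
    SD imputation through publication-bias diagnostics can run with no
    download.

A single master seed spawns one independent stream per table, so adding
a table never perturbs existing draws; identical seeds give identical
outputs.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .effects import METRICS
from .environ import cbm_daylength, median_experiment_doy
from .phylo import correlation_matrix, read_tree

__all__ = ["SyntheticConfig", "simulate_tree", "simulate_effects", "simulate_dataset",
           "small_study_selection"]

# effect-size mix over outcome metrics, matching the observed literature
# (fruit set dominates, then seed set; mass and pollen outcomes are rare)
DEFAULT_METRICS_MIX = {
    "fruit_set": 0.56,
    "seed_set": 0.35,
    "fruit_mass": 0.04,
    "seed_mass": 0.03,
    "pollen_deposition": 0.02,
}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for simulation and recovery tests."""

    n_studies: int = 120
    n_species: int = 130
    species_per_study: int = 2
    groups_per_study: int = 3
    metrics_mix: dict = field(default_factory=lambda: dict(DEFAULT_METRICS_MIX))
    # (overall SMD, exposure-quotient slope): no overall diel difference,
    # a modest negative exposure-imbalance bias
    beta: tuple = (0.0, -0.1)
    # study, metric, species_phylo, species_nonphylo, observation
    sigma2: dict = field(
        default_factory=lambda: {
            "study": 0.2,
            "metric": 0.02,
            "species_phylo": 0.05,
            "species_nonphylo": 0.5,
            "obs": 0.3,
        }
    )
    n_range: tuple = (10, 40)
    sd_scale: float = 0.3
    missing_sd_rate: float = 0.03
    open_prob: float = 0.84
    closed_prob: float = 0.65
    seed: int = 0

    def validate(self):
        if any(v < 0 for v in self.sigma2.values()):
            raise ValueError("variance components must be >= 0")
        if abs(sum(self.metrics_mix.values()) - 1.0) > 1e-9:
            raise ValueError("metric proportions must sum to 1")
        return self


def simulate_tree(n_species: int, seed: int) -> str:
    """Ultrametric pure-birth tree on n species, height normalised to 1.

    Tips are named ``GenusXX_spYYY`` with genera shared by consecutive
    triples, so genus-level grafting has anchors to resolve.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=_pyrandom.Random(int(seed)),
    )
    leaves = list(tree.leaf_node_iter())
    height = max(lf.distance_from_root() for lf in leaves)
    tree.seed_node.edge.length = None
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    # square up any residual numerical drift in tip depths
    for lf in tree.leaf_node_iter():
        lf.edge.length += 1.0 - lf.distance_from_root()
    for i, lf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        lf.taxon.label = f"Genus{i // 3:02d}_sp{i:03d}"
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)


def _draw_random_effects(cfg: SyntheticConfig, R: np.ndarray, rng) -> dict:
    s2 = cfg.sigma2
    L = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
    return {
        "study": rng.normal(0, np.sqrt(s2["study"]), cfg.n_studies),
        "metric": rng.normal(0, np.sqrt(s2["metric"]), len(METRICS)),
        "species_phylo": np.sqrt(s2["species_phylo"]) * (L @ rng.standard_normal(R.shape[0])),
        "species_nonphylo": rng.normal(0, np.sqrt(s2["species_nonphylo"]), R.shape[0]),
    }


def _design(cfg: SyntheticConfig, rng):
    """Study-level geography and the per-group keys (study, species, metric)."""
    lat = np.clip(rng.normal(30, 18, cfg.n_studies), -45, 65)
    start = rng.integers(1, 13, cfg.n_studies)
    end = (start - 1 + rng.integers(0, 4, cfg.n_studies)) % 12 + 1
    year = rng.integers(1962, 2023, cfg.n_studies)
    metric_names = list(cfg.metrics_mix)
    metric_p = np.array([cfg.metrics_mix[m] for m in metric_names])
    rows = []
    for s in range(cfg.n_studies):
        sp_pool = rng.choice(cfg.n_species, size=min(cfg.species_per_study, cfg.n_species),
                             replace=False)
        doy = median_experiment_doy(int(start[s]), int(end[s]), int(year[s]))
        daylength = cbm_daylength(float(lat[s]), doy)
        used = set()
        for g in range(cfg.groups_per_study):
            sp = int(sp_pool[g % len(sp_pool)])
            metric = metric_names[int(rng.choice(len(metric_names), p=metric_p))]
            for _ in range(25):  # keep study x species x metric groups unique
                if (sp, metric) not in used:
                    break
                sp = int(rng.choice(cfg.n_species))
                metric = metric_names[int(rng.choice(len(metric_names), p=metric_p))]
            used.add((sp, metric))
            rows.append(
                {
                    "study": s,
                    "species": sp,
                    "metric": metric,
                    "daylength_h": daylength,
                    "study_year": int(year[s]),
                    "latitude": float(lat[s]),
                    "start_month": int(start[s]),
                    "end_month": int(end[s]),
                }
            )
    return pd.DataFrame(rows)


def simulate_effects(cfg: SyntheticConfig, seed: int | None = None):
    """Model-exact effect-level simulation for the night-vs-day comparison.

    Returns ``(effects, truth)`` where effects has columns yi, vi,
    exposure_quotient and the grouping labels, and truth records the
    generating parameters, tree and correlation matrix.
    """
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)]
    rng_tree, rng_u, rng_obs = streams
    newick = simulate_tree(cfg.n_species, int(rng_tree.integers(2**31 - 1)))
    corr = correlation_matrix(read_tree(newick))
    R = corr.R
    u = _draw_random_effects(cfg, R, rng_u)

    des = _design(cfg, rng_obs)
    k = len(des)
    quot = des["daylength_h"] / (24.0 - des["daylength_h"])
    metric_idx = des["metric"].map({m: i for i, m in enumerate(METRICS)}).to_numpy()
    theta = (
        cfg.beta[0]
        + cfg.beta[1] * quot.to_numpy()
        + u["study"][des["study"]]
        + u["metric"][metric_idx]
        + u["species_phylo"][des["species"]]
        + u["species_nonphylo"][des["species"]]
        + rng_obs.normal(0, np.sqrt(cfg.sigma2["obs"]), k)
    )
    n = rng_obs.integers(cfg.n_range[0], cfg.n_range[1] + 1, k)
    # known sampling variance: the usual SMD form evaluated at the fixed
    # part of the true effect, so vi is independent of the random effects
    # (keeps the generator model-exact for sharp recovery checks)
    theta_fixed = cfg.beta[0] + cfg.beta[1] * quot.to_numpy()
    vi = (2.0 * n) / (n * n) + theta_fixed**2 / (2.0 * (2 * n))
    yi = rng_obs.normal(theta, np.sqrt(vi))
    effects = pd.DataFrame(
        {
            "comparison": "night_vs_day",
            "study_id": des["study"].map(lambda s: f"S{s:03d}"),
            "species": des["species"].map(lambda i: corr.species[i]),
            "metric": des["metric"],
            "yi": yi,
            "vi": vi,
            "exposure_quotient": quot,
            "pub_year": des["study_year"] + 5,
            "obs_id": [f"obs{i:04d}" for i in range(k)],
        }
    )
    truth = {"beta": cfg.beta, "sigma2": dict(cfg.sigma2), "newick": newick,
             "corr": corr, "theta": theta}
    return effects, truth


def _gaussian_arm(rng, mu, sigma, n):
    mean = rng.normal(mu, sigma / np.sqrt(n))
    sd = sigma * np.sqrt(rng.chisquare(n - 1) / (n - 1))
    return mean, max(sd, 1e-12)


def simulate_dataset(cfg: SyntheticConfig, seed: int | None = None):
    """Full synthetic input set: (treatments, traits, env, newick).

    Gaussian outcome arms are generated so the computed Hedges' g is
    centred on the group's true SMD; fruit-set groups are emitted as
    binomial (n_fruits, n_flowers) counts whose success probabilities
    induce the target SMD approximately. Infeasible proportion targets
    are clipped and counted in ``env.attrs['clipped_targets']``.
    """
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).spawn(5)
    rng_tree, rng_u, rng_design, rng_arm, rng_traits = [np.random.default_rng(s) for s in ss]

    newick = simulate_tree(cfg.n_species, int(rng_tree.integers(2**31 - 1)))
    corr = correlation_matrix(read_tree(newick))
    u = _draw_random_effects(cfg, corr.R, rng_u)
    des = _design(cfg, rng_design)

    arm_base = {"day": 0.0}
    rows = []
    clipped = 0
    for i, grp in des.iterrows():
        sp_name = corr.species[grp["species"]]
        mi = METRICS.index(grp["metric"])
        base = (
            cfg.beta[0]
            + u["study"][grp["study"]]
            + u["metric"][mi]
            + u["species_phylo"][grp["species"]]
            + u["species_nonphylo"][grp["species"]]
        )
        quot = grp["daylength_h"] / (24.0 - grp["daylength_h"])
        theta_nd = base + cfg.beta[1] * quot + rng_arm.normal(0, np.sqrt(cfg.sigma2["obs"]))
        arms = ["day", "night"]
        if rng_arm.random() < cfg.open_prob:
            arms.append("open")
            if rng_arm.random() < cfg.closed_prob:
                arms.append("closed")
        # arm-level true means on the outcome scale, in pooled-SD units
        offsets = {"day": 0.0, "night": theta_nd,
                   "open": max(theta_nd, 0.0) + 0.4, "closed": min(theta_nd, 0.0) - 0.8}
        common = {
            "study_id": f"S{grp['study']:03d}",
            "species": sp_name,
            "metric": grp["metric"],
            "study_year": grp["study_year"],
            "latitude": grp["latitude"],
            "longitude": 0.0,
            "start_month": grp["start_month"],
            "end_month": grp["end_month"],
        }
        if grp["metric"] == "fruit_set":
            p0 = rng_arm.uniform(0.15, 0.6)
            for arm in arms:
                n_flowers = int(rng_arm.integers(cfg.n_range[0], cfg.n_range[1] + 1))
                target = p0 + offsets[arm] * np.sqrt(p0 * (1 - p0))
                p = float(np.clip(target, 0.02, 0.98))
                clipped += int(p != target)
                n_fruits = int(rng_arm.binomial(n_flowers, p))
                rows.append({**common, "treatment": arm, "n": n_flowers,
                             "mean": n_fruits / n_flowers, "sd": np.nan,
                             "n_flowers": n_flowers, "n_fruits": n_fruits})
        else:
            mu0 = float(rng_arm.lognormal(np.log(20.0), 0.5))
            sigma0 = cfg.sd_scale * mu0
            for arm in arms:
                n = int(rng_arm.integers(cfg.n_range[0], cfg.n_range[1] + 1))
                mean, sd = _gaussian_arm(rng_arm, mu0 + offsets[arm] * sigma0, sigma0, n)
                rows.append({**common, "treatment": arm, "n": n, "mean": mean, "sd": sd,
                             "n_flowers": np.nan, "n_fruits": np.nan})
    treatments = pd.DataFrame(rows)

    # missing-SD mask on non-fruit-set rows
    cand = treatments.index[treatments["metric"] != "fruit_set"]
    mask = cand[rng_arm.random(len(cand)) < cfg.missing_sd_rate]
    treatments.loc[mask, "sd"] = np.nan

    # publication year (study year + lag); a few studies missing study year
    lag = np.maximum(np.round(rng_design.normal(4.9, 1.5, cfg.n_studies)), 0).astype(int)
    study_ids = [f"S{s:03d}" for s in range(cfg.n_studies)]
    year_map = des.drop_duplicates("study").set_index("study")["study_year"]
    pub_year = {f"S{s:03d}": int(year_map.get(s, 2000)) + int(lag[s]) for s in range(cfg.n_studies)}
    treatments["pub_year"] = treatments["study_id"].map(pub_year)
    drop_year = rng_design.random(cfg.n_studies) < 0.02
    lost = {sid for sid, d in zip(study_ids, drop_year) if d}
    treatments.loc[treatments["study_id"].isin(lost), "study_year"] = np.nan
    # exposure hours stated for ~70% of studies, otherwise left for imputation
    stated = rng_design.random(cfg.n_studies) < 0.7
    day_h = {sid: (12.0 if st else np.nan) for sid, st in zip(study_ids, stated)}
    treatments["day_exposure_h"] = treatments["study_id"].map(day_h)
    treatments["night_exposure_h"] = 24.0 - treatments["day_exposure_h"]

    traits = _simulate_traits(corr.species, rng_traits)
    env = pd.DataFrame(
        {
            "study_id": study_ids,
            "dtr_C": np.clip(rng_traits.normal(13.0, 3.7, cfg.n_studies), 2.0, None),
            "elevation_m": np.abs(rng_traits.normal(678.0, 749.0, cfg.n_studies)),
        }
    )
    env.attrs["clipped_targets"] = clipped
    return treatments, traits, env, newick


def _simulate_traits(species: list, rng) -> pd.DataFrame:
    n = len(species)
    log_len = rng.normal(np.log(25), 0.5, n)
    width = np.exp(log_len + rng.normal(0, 0.15, n) - 0.4)
    style = np.exp(log_len + rng.normal(0, 0.2, n) - 0.7)
    anthesis = rng.choice(["day", "night", "both"], n, p=[0.45, 0.3, 0.25]).astype(object)
    anthesis[rng.random(n) < 0.15] = None
    return pd.DataFrame(
        {
            "species": species,
            "lifespan": rng.choice(["annual", "perennial"], n, p=[0.3, 0.7]),
            "life_form": rng.choice(["herb", "shrub", "tree", "succulent"], n),
            "photosynthetic_pathway": rng.choice(["C3", "CAM", "C4"], n, p=[0.7, 0.2, 0.1]),
            "breeding_system": rng.choice(["hermaphrodite", "monoecious", "dioecious"], n,
                                          p=[0.7, 0.15, 0.15]),
            "flower_colour": rng.choice(["white", "yellow", "purple", "pink", "orange", "red",
                                         "green", "blue", "brown"], n),
            "flower_symmetry": rng.choice(["actinomorphic", "zygomorphic"], n, p=[0.7, 0.3]),
            "flower_shape": rng.choice(["tube", "open", "bell", "capitulum"], n,
                                       p=[0.4, 0.35, 0.2, 0.05]),
            "anthesis_time": anthesis,
            "nectar_presence": rng.choice(["yes", "no"], n, p=[0.8, 0.2]),
            "odour_presence": rng.choice(["yes", "no"], n, p=[0.6, 0.4]),
            "flower_width_mm": width,
            "flower_length_mm": np.exp(log_len),
            "style_length_mm": style,
            "plant_height_m": np.exp(rng.normal(0.0, 0.8, n)),
            "crop_status": rng.choice(["wild", "crop"], n, p=[0.87, 0.13]),
        }
    )


def small_study_selection(effects: pd.DataFrame, rng, drop_prob: float = 0.9) -> pd.DataFrame:
    """Suppress small studies that did not find a significantly positive effect.

    Rows with se above the median are dropped with probability
    ``drop_prob`` unless yi/se > 1.96 — the classic one-directional
    selection process that produces funnel asymmetry, used by the
    publication-bias power checks. (Sign-symmetric suppression leaves the
    funnel symmetric and is undetectable by design.)
    """
    se = np.sqrt(effects["vi"].to_numpy(dtype=float))
    z = effects["yi"].to_numpy(dtype=float) / se
    at_risk = (z < 1.96) & (se > np.median(se))
    drop = at_risk & (rng.random(len(effects)) < drop_prob)
    return effects.loc[~drop].copy()
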