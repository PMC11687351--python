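"""Moderator table construction: trait recoding, collinearity screening
and the per-moderator model set.

Because the candidate moderators are strongly interdependent, each one is
tested in its own single-moderator meta-regression (always alongside the
diel exposure quotient and the full random structure), with linear and
quadratic variants for continuous variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_CODEBOOK",
    "EXCLUDED_SPECIES",
    "recode_traits",
    "collinearity_screen",
    "ModelSpec",
    "build_model_set",
    "CONTINUOUS_MODERATORS",
    "CATEGORICAL_MODERATORS",
]

# recode rules: column -> {raw level: recoded level}
DEFAULT_CODEBOOK = {
    "flower_shape": {"capitulum": "open"},
    "flower_colour": {"blue": "purple", "brown": "yellow"},
}

# holoparasite lacking photosynthesis; cannot be assigned a pathway
EXCLUDED_SPECIES = ("Mitrastemon yamamotoi",)

CONTINUOUS_MODERATORS = ["daylength_h", "dtr_C", "elevation_m", "style_length_mm",
                         "plant_height_m", "dependency_smd"]
CATEGORICAL_MODERATORS = ["metric", "lifespan", "life_form", "photosynthetic_pathway",
                          "breeding_system", "flower_colour", "flower_symmetry",
                          "flower_shape", "anthesis_time", "nectar_presence",
                          "odour_presence", "crop_status"]


def recode_traits(records: pd.DataFrame, codebook: dict | None = None) -> tuple[pd.DataFrame, list]:
    """Apply the trait recodes and species exclusions; returns (records, log).

    Rules: capitulum flowers -> open, blue -> purple, brown -> yellow,
    missing anthesis time -> "both", and the excluded species dropped.
    Idempotent; every applied rule is logged.
    """
    codebook = DEFAULT_CODEBOOK if codebook is None else codebook
    out = records.copy()
    log = []
    for col, mapping in codebook.items():
        if col not in out.columns:
            continue
        for raw, new in mapping.items():
            hit = out[col] == raw
            if hit.any():
                out.loc[hit, col] = new
                log.append(f"recode {col}: {raw} -> {new} ({int(hit.sum())} records)")
    if "anthesis_time" in out.columns:
        miss = out["anthesis_time"].isna()
        if miss.any():
            out.loc[miss, "anthesis_time"] = "both"
            log.append(f"anthesis_time missing -> both ({int(miss.sum())} records)")
        bad = set(out["anthesis_time"]) - {"day", "night", "both"}
        if bad:
            raise ValueError(f"unknown anthesis_time levels: {sorted(bad)}")
    drop = out["species"].isin(EXCLUDED_SPECIES)
    if drop.any():
        out = out.loc[~drop].copy()
        log.append(f"excluded species: {', '.join(EXCLUDED_SPECIES)} ({int(drop.sum())} records)")
    return out, log


def _cramers_v(a: pd.Series, b: pd.Series) -> float:
    tab = pd.crosstab(a, b)
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    r, c = tab.shape
    denom = n * (min(r, c) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else np.nan

def _anova_r2(x: pd.Series, g: pd.Series) -> float:
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst == 0:
        return np.nan
    sse = float(x.groupby(g, observed=True).apply(lambda v: ((v - v.mean()) ** 2).sum()).sum())
    return 1.0 - sse / sst


def collinearity_screen(
    table: pd.DataFrame,
    continuous: list[str],
    nominal: list[str],
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Pairwise association screen over candidate moderators.

    Pearson's r between continuous pairs, Cramer's V between nominal
    pairs, and the R^2 of a one-way fit for mixed pairs. Pairs with fewer
    than 3 complete cases or a constant member report NaN with a warning
    flag; |measure| > threshold is flagged as highly associated.
    """
    vars_ = [(v, "continuous") for v in continuous] + [(v, "nominal") for v in nominal]
    rows = []
    for i, (v1, k1) in enumerate(vars_):
        for v2, k2 in vars_[i:]:
            sub = table[[v1, v2]].dropna() if v1 != v2 else table[[v1]].dropna()
            value, kind, warn = np.nan, None, None
            if v1 == v2:
                kind = "self"
                value = 1.0
            elif len(sub) < 3:
                warn = "fewer than 3 complete cases"
            elif k1 == k2 == "continuous":
                kind = "pearson_r"
                if sub[v1].nunique() < 2 or sub[v2].nunique() < 2:
                    warn = "constant variable"
                else:
                    value = float(stats.pearsonr(sub[v1], sub[v2])[0])
            elif k1 == k2 == "nominal":
                kind = "cramers_v"
                if sub[v1].nunique() < 2 or sub[v2].nunique() < 2:
                    warn = "constant variable"
                else:
                    value = _cramers_v(sub[v1], sub[v2])
            else:
                kind = "r2"
                x, g = (v1, v2) if k1 == "continuous" else (v2, v1)
                if sub[x].nunique() < 2 or sub[g].nunique() < 2:
                    warn = "constant variable"
                else:
                    value = _anova_r2(sub[x], sub[g])
            rows.append(
                {
                    "var1": v1,
                    "var2": v2,
                    "kind": kind,
                    "value": value,
                    "flagged": bool(np.isfinite(value) and abs(value) > threshold and v1 != v2),
                    "warning": warn,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ModelSpec:
    """Recipe for one meta-regression: a moderator plus the standard
    fixed (exposure quotient) and random structure."""

    comparison: str
    moderator: str | None
    kind: str  # "none" | "continuous" | "categorical"
    quadratic: bool = False
    random_preset: str = "full"  # "full" or "reduced" (drops the metric term)
    subset: str | None = None    # e.g. restrict to rows with a dependency value

    @property
    def label(self) -> str:
        mod = self.moderator or "overall"
        return f"{self.comparison}:{mod}" + ("^2" if self.quadratic else "")


def build_model_set(
    effects: pd.DataFrame,
    comparison: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> tuple[list[ModelSpec], list[str]]:
    """One single-moderator spec per moderator (two for continuous ones:
    linear, and linear+quadratic). Moderators left with a single observed
    level (or no variation) in this comparison's rows are skipped and
    logged. The outcome-metric moderator uses the reduced random
    structure, which drops the metric random term."""
    continuous = CONTINUOUS_MODERATORS if continuous is None else continuous
    categorical = CATEGORICAL_MODERATORS if categorical is None else categorical
    sub = effects.loc[effects["comparison"] == comparison]
    specs, log = [], []
    for mod in continuous:
        if mod not in sub.columns or sub[mod].dropna().nunique() < 2:
            log.append(f"skip {mod}: absent or constant in {comparison}")
            continue
        subset = "dependency" if mod == "dependency_smd" else None
        specs.append(ModelSpec(comparison, mod, "continuous", quadratic=False, subset=subset))
        specs.append(ModelSpec(comparison, mod, "continuous", quadratic=True, subset=subset))
    for mod in categorical:
        if mod not in sub.columns or sub[mod].dropna().nunique() < 2:
            log.append(f"skip {mod}: absent or single level in {comparison}")
            continue
        preset = "reduced" if mod == "metric" else "full"
        specs.append(ModelSpec(comparison, mod, "categorical", random_preset=preset))
    return specs, log
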