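"""Standardised mean differences (Hedges' g) from treatment-level summaries.

Each pollinator-exclusion experiment contributes up to four arms per
study x species x outcome metric: ``day`` (night pollinators excluded),
``night`` (day pollinators excluded), ``open`` (never bagged) and
``closed`` (always bagged). From these we form up to four comparisons:

- ``night_vs_day`` (focal = night): yi > 0 means night pollination was
  more effective than day pollination;
- ``day_vs_open`` and ``night_vs_open`` (focal = diel arm): yi < 0 means
  the single diel period was less effective than open pollination;
- ``open_vs_closed`` (focal = open): the plant's pollination dependency.

Group ordering is fixed in code, never inferred from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pooled_sd",
    "hedges_g",
    "binomial_sd",
    "build_comparisons",
    "filter_outliers",
    "COMPARISONS",
    "TREATMENTS",
    "METRICS",
]

TREATMENTS = ("day", "night", "open", "closed")
METRICS = ("fruit_set", "fruit_mass", "seed_set", "seed_mass", "pollen_deposition")

# comparison -> (focal arm, reference arm)
COMPARISONS = {
    "night_vs_day": ("night", "day"),
    "day_vs_open": ("day", "open"),
    "night_vs_open": ("night", "open"),
    "open_vs_closed": ("open", "closed"),
}

OUTLIER_SMD = 10.0


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> tuple[float, bool]:
    """Pooled standard deviation of two arms.

    Returns ``(sp, degenerate)`` where ``degenerate`` flags sp == 0.
    """
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        raise ValueError("pooled SD needs n1, n2 >= 1 and n1 + n2 >= 3")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return sp, sp == 0.0


def hedges_g(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Hedges' g and its sampling variance for focal arm 1 vs reference arm 2.

    g = J * (m1 - m2) / sp with the small-sample correction
    J = 1 - 3 / (4 (n1 + n2 - 2) - 1), and

        vi = (n1 + n2) / (n1 n2) + g^2 / (2 (n1 + n2)).

    The variance uses the bias-corrected g in the quadratic term (the
    convention of the common escalc implementation); the uncorrected-d
    alternative differs only at O(1/n^2).
    """
    sp, degenerate = pooled_sd(sd1, n1, sd2, n2)
    ntot = n1 + n2
    base_v = ntot / (n1 * n2)
    if degenerate:
        if m1 == m2:
            return 0.0, base_v
        raise ValueError("undefined SMD: zero pooled SD with unequal means")
    j = 1.0 - 3.0 / (4.0 * (ntot - 2) - 1.0)
    yi = j * (m1 - m2) / sp
    vi = base_v + yi**2 / (2.0 * ntot)
    return yi, vi


def binomial_sd(n_fruits: int, n_flowers: int) -> tuple[float, float]:
    """Theoretical per-flower mean and SD of a fruit-set proportion.

    Treats fruit set of ``n_flowers`` flowers as Bernoulli trials: the
    mean is the raw proportion and the SD is sqrt(p (1 - p)). For
    all-or-nothing arms (0 or n fruits) the SD (only) uses the
    continuity-corrected p = (x + 0.5) / (n + 1) so it stays positive.
    """
    if n_flowers < 1:
        raise ValueError("n_flowers must be >= 1")
    if not 0 <= n_fruits <= n_flowers:
        raise ValueError("need 0 <= n_fruits <= n_flowers")
    mean = n_fruits / n_flowers
    if n_fruits in (0, n_flowers):
        p = (n_fruits + 0.5) / (n_flowers + 1.0)
    else:
        p = mean
    return mean, math.sqrt(p * (1.0 - p))


_GROUP = ["study_id", "species", "metric"]


def build_comparisons(rows: pd.DataFrame) -> pd.DataFrame:
    """Emit one effect size per available treatment comparison.

    ``rows`` holds one arm per row with columns study_id, species,
    metric, treatment, n, mean, sd (no missing sd at this stage). Extra
    columns constant within a group (study metadata) are carried through.
    """
    df = rows.copy()
    required = _GROUP + ["treatment", "n", "mean", "sd"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if df["sd"].isna().any():
        bad = df.loc[df["sd"].isna(), _GROUP].drop_duplicates()
        raise ValueError(f"missing SD after imputation stage for groups:\n{bad}")
    dup = df.duplicated(subset=_GROUP + ["treatment"], keep=False)
    if dup.any():
        keys = df.loc[dup, _GROUP + ["treatment"]].drop_duplicates()
        raise ValueError(f"duplicate treatment arms:\n{keys}")

    carry = [c for c in df.columns if c not in required]
    out = []
    for key, grp in df.groupby(_GROUP, sort=False):
        arms = {row.treatment: row for row in grp.itertuples()}
        extras = {c: grp.iloc[0][c] for c in carry}
        for comp, (focal, ref) in COMPARISONS.items():
            if focal not in arms or ref not in arms:
                continue
            a, b = arms[focal], arms[ref]
            yi, vi = hedges_g(a.mean, a.sd, int(a.n), b.mean, b.sd, int(b.n))
            out.append(
                {
                    "comparison": comp,
                    "study_id": key[0],
                    "species": key[1],
                    "metric": key[2],
                    "yi": yi,
                    "vi": vi,
                    "n_focal": int(a.n),
                    "n_ref": int(b.n),
                    **extras,
                }
            )
    return pd.DataFrame(out)


def filter_outliers(effects: pd.DataFrame, threshold: float = OUTLIER_SMD) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split effects into (kept, removed) by the |SMD| > threshold rule.

    The boundary is strict: |yi| exactly equal to the threshold is kept.
    Input row order is preserved in both outputs.
    """
    extreme = effects["yi"].abs() > threshold
    return effects.loc[~extreme].copy(), effects.loc[extreme].copy()
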