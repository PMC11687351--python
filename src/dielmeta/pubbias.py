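"""Publication-bias and sensitivity diagnostics on the multilevel model.

The Egger-style test regresses the SMD on its standard error inside the
multilevel model (random structure retained); a model intercept
significantly different from zero indicates funnel asymmetry /
small-study effects. The time-lag test adds (centred) publication year as
a moderator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .meta import RandomEffect, reml_fit

__all__ = ["egger_multilevel", "time_lag_test", "funnel_data"]


def egger_multilevel(effects: pd.DataFrame, random, X=None, coef_names=None):
    """Multilevel Egger regression: SMD on its SE within the fitted model.

    The SE moderator is deliberately uncentred so the intercept keeps its
    "effect at SE = 0" interpretation. Returns ``(intercept, z, p, fit)``.
    """
    y = effects["yi"].to_numpy(dtype=float)
    vi = effects["vi"].to_numpy(dtype=float)
    se = np.sqrt(vi)
    if X is None:
        X = np.ones((len(y), 1))
        coef_names = ["intercept"]
    X2 = np.column_stack([X, se])
    names = list(coef_names) + ["se"]
    fit = reml_fit(y, vi, X2, random, coef_names=names)
    row = fit.coef.iloc[0]
    return float(row["estimate"]), float(row["zval"]), float(row["pval"]), fit


def time_lag_test(effects: pd.DataFrame, random, year_col: str = "pub_year", X=None, coef_names=None):
    """Time-lag (decline-effect) test: SMD on centred publication year.

    Returns ``(slope, z, p, fit)``.
    """
    years = effects[year_col].to_numpy(dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("time-lag test needs more than one distinct publication year")
    y = effects["yi"].to_numpy(dtype=float)
    vi = effects["vi"].to_numpy(dtype=float)
    yr = years - years.mean()
    if X is None:
        X = np.ones((len(y), 1))
        coef_names = ["intercept"]
    X2 = np.column_stack([X, yr])
    names = list(coef_names) + ["year_centred"]
    fit = reml_fit(y, vi, X2, random, coef_names=names)
    row = fit.coef.iloc[len(names) - 1]
    return float(row["estimate"]), float(row["zval"]), float(row["pval"]), fit


def funnel_data(effects: pd.DataFrame) -> pd.DataFrame:
    """Plotting-ready funnel table: yi against se = sqrt(vi)."""
    return pd.DataFrame({"yi": effects["yi"].to_numpy(dtype=float),
                         "se": np.sqrt(effects["vi"].to_numpy(dtype=float))})
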