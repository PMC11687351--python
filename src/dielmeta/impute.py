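"""Regression-based imputation of missing standard deviations, study years
and exposure hours.

Missing SDs are predicted, within each outcome metric, from the arm's
sample size, mean and treatment (day / night / open). Seed set uses the
full factorial n x mean x treatment design; the sparser metrics use
additive terms only. Observed SDs are never altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "SDImputationModel",
    "fit_sd_model",
    "impute_sd",
    "apply_sd_imputation",
    "mean_publication_lag",
    "impute_study_year",
    "impute_exposure_hours",
]

SD_FLOOR_FRACTION = 0.01  # floor: 1% of the arm mean
SD_FLOOR_ABS = 1e-8

_INTERACTION_METRICS = {"seed_set"}


@dataclass
class SDImputationModel:
    metric: str
    formula_kind: str  # "interactions" | "additive"
    result: object     # fitted statsmodels OLS results

    @property
    def r2(self) -> float:
        return float(self.result.rsquared)

    @property
    def fvalue(self) -> float:
        return float(self.result.fvalue)

    @property
    def df(self) -> tuple[int, int]:
        return int(self.result.df_model), int(self.result.df_resid)


def fit_sd_model(rows: pd.DataFrame, metric: str) -> SDImputationModel:
    """Least-squares model of SD on n, mean and treatment for one metric."""
    sub = rows.loc[(rows["metric"] == metric) & rows["sd"].notna()].copy()
    kind = "interactions" if metric in _INTERACTION_METRICS else "additive"
    formula = (
        "sd ~ n * mean * C(treatment)" if kind == "interactions" else "sd ~ n + mean + C(treatment)"
    )
    res = smf.ols(formula, data=sub).fit()
    if int(res.df_resid) < 1 or sub.shape[0] < res.df_model + 2:
        raise ValueError(f"too few complete rows to fit the SD model for {metric!r}")
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise ValueError(f"rank-deficient SD design for {metric!r}: {res.model.exog_names}")
    return SDImputationModel(metric=metric, formula_kind=kind, result=res)


def impute_sd(model: SDImputationModel, row) -> tuple[float, bool]:
    """Predicted SD for one arm, floored at a small positive value.

    Returns ``(sd, floored)``; ``floored`` flags a raw prediction below
    the floor (e.g. a negative linear prediction).
    """
    frame = pd.DataFrame([{"n": row["n"], "mean": row["mean"], "treatment": row["treatment"]}])
    raw = float(model.result.predict(frame).iloc[0])
    floor = max(SD_FLOOR_FRACTION * float(row["mean"]), SD_FLOOR_ABS)
    return (max(raw, floor), raw < floor)


def apply_sd_imputation(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill all missing SDs; returns (rows, report).

    Models are fitted per metric on the complete rows of that metric.
    The report lists one row per imputation with the source model's R^2.
    """
    out = rows.copy()
    report = []
    for metric in out.loc[out["sd"].isna(), "metric"].unique():
        model = fit_sd_model(out, metric)
        mask = (out["metric"] == metric) & out["sd"].isna()
        for idx in out.index[mask]:
            sd, floored = impute_sd(model, out.loc[idx])
            out.loc[idx, "sd"] = sd
            report.append(
                {
                    "row": idx,
                    "study_id": out.loc[idx, "study_id"],
                    "metric": metric,
                    "imputed_sd": sd,
                    "floored": floored,
                    "model_r2": model.r2,
                }
            )
    return out, pd.DataFrame(report)


def mean_publication_lag(study_years, pub_years) -> float:
    """Average publication lag (publication year minus study year) over
    rows where both are known."""
    s = pd.Series(study_years, dtype=float)
    p = pd.Series(pub_years, dtype=float)
    ok = s.notna() & p.notna()
    if not ok.any():
        raise ValueError("no rows with both study and publication year")
    return float((p[ok] - s[ok]).mean())


def impute_study_year(pub_year: int, mean_lag: float) -> int:
    """Impute a study year as the publication year minus the average lag."""
    return int(math.floor(pub_year - mean_lag + 0.5))


def impute_exposure_hours(
    day_hours: float | None, night_hours: float | None, daylength_hours: float
) -> tuple[float, float]:
    """Stated exposure hours pass through; otherwise use the photoperiod.

    Imputed values satisfy day + night = 24 exactly.
    """
    stated = day_hours is not None and night_hours is not None \
        and not (pd.isna(day_hours) or pd.isna(night_hours))
    if stated:
        return float(day_hours), float(night_hours)
    if not 0.0 <= daylength_hours <= 24.0:
        raise ValueError("daylength must lie in [0, 24]")
    return float(daylength_hours), 24.0 - float(daylength_hours)
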