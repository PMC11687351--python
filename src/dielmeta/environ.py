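"""Photoperiod and diel exposure covariates.

Daylength follows the CBM model of Forsythe et al.: solar declination is
approximated from the day of year, and the fraction of the day the sun is
above a horizon-angle threshold ``p`` (degrees) gives the daylength. The
default p = 0.8333 degrees corresponds to sunrise/sunset including
atmospheric refraction; p = 0 gives the sun-centre definition.
"""

from __future__ import annotations

import datetime as _dt
import math

import pandas as pd

__all__ = ["cbm_daylength", "median_experiment_doy", "exposure_quotient", "join_covariates"]


def cbm_daylength(latitude_deg: float, day_of_year: int, p_coef: float = 0.8333) -> float:
    """Daylength in hours at a latitude and day of year (CBM model).

    theta is the solar orbital angle, phi the solar declination. Polar
    day/night fall out of clamping the acos argument to [-1, 1],
    returning 24 or 0 exactly.
    """
    if not -90.0 <= latitude_deg <= 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    if not 1 <= day_of_year <= 366:
        raise ValueError("day_of_year must lie in [1, 366]")
    j = day_of_year
    theta = 0.2163108 + 2.0 * math.atan(0.9671396 * math.tan(0.00860 * (j - 186)))
    phi = math.asin(0.39795 * math.cos(theta))
    lat = math.radians(latitude_deg)
    num = math.sin(math.radians(p_coef)) + math.sin(lat) * math.sin(phi)
    den = math.cos(lat) * math.cos(phi)
    x = num / den if den != 0 else math.inf * (1 if num >= 0 else -1)
    x = min(1.0, max(-1.0, x))
    return 24.0 - (24.0 / math.pi) * math.acos(x)


def median_experiment_doy(start_month: int, end_month: int, year: int) -> int:
    """Day of year of the midpoint between the 15th of the start and end months.

    If ``end_month < start_month`` the experiment wraps the year boundary
    and the end anchor falls in the following year; the returned day of
    year is that of the midpoint date in its own calendar year.
    """
    for m in (start_month, end_month):
        if not 1 <= int(m) <= 12:
            raise ValueError(f"invalid month {m}")
    start_month, end_month, year = int(start_month), int(end_month), int(year)
    span_end = end_month + (12 if end_month < start_month else 0)
    mid2 = start_month + span_end  # twice the midpoint month
    mm, half = divmod(mid2, 2)
    mid_year = year + (mm - 1) // 12
    mid = _dt.date(mid_year, (mm - 1) % 12 + 1, 15)
    if half:  # odd month span: halfway to the 15th of the following month
        nxt_mm = mm + 1
        nxt = _dt.date(year + (nxt_mm - 1) // 12, (nxt_mm - 1) % 12 + 1, 15)
        mid = mid + (nxt - mid) / 2
    return int(mid.timetuple().tm_yday)


def exposure_quotient(comparison: str, day_hours: float, night_hours: float) -> float:
    """Diel exposure quotient for one comparison.

    night_vs_day -> day/night hours; the open comparisons relate the diel
    period to the full 24-h day; open_vs_closed has no diel imbalance and
    returns 1.
    """
    if comparison == "open_vs_closed":
        return 1.0
    if day_hours <= 0 or night_hours <= 0:
        raise ValueError("exposure hours must be positive")
    if comparison == "night_vs_day":
        return day_hours / night_hours
    if comparison == "day_vs_open":
        return day_hours / 24.0
    if comparison == "night_vs_open":
        return night_hours / 24.0
    raise ValueError(f"unknown comparison {comparison!r}")


def join_covariates(studies: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Left-join precomputed per-study covariates (daily temperature range,
    elevation) onto a study table keyed by ``study_id``."""
    if covariates is None:
        return studies
    cov = covariates.drop_duplicates(subset="study_id")
    return studies.merge(cov, on="study_id", how="left", validate="many_to_one")
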