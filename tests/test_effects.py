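"""Effect-size construction: pooled SD, Hedges' g, binomial arms,
comparison assembly, sign conventions and outlier filtering."""

import math

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from dielmeta.effects import (binomial_sd, build_comparisons, filter_outliers,
                              hedges_g, pooled_sd)


@pytest.mark.parametrize(
    "sd1,n1,sd2,n2,expected,degenerate",
    [
        (1.0, 10, 1.0, 10, 1.0, False),
        (0.0, 5, 0.0, 5, 0.0, True),
        (2.0, 4, 1.0, 6, math.sqrt((3 * 4 + 5 * 1) / 8), False),
    ],
)
def test_pooled_sd_examples(sd1, n1, sd2, n2, expected, degenerate):
    sp, flag = pooled_sd(sd1, n1, sd2, n2)
    assert sp == pytest.approx(expected)
    assert flag is degenerate


def test_pooled_sd_preconditions():
    with pytest.raises(ValueError):
        pooled_sd(1.0, 1, 1.0, 1)
    with pytest.raises(ValueError):
        pooled_sd(-0.1, 5, 1.0, 5)


def test_hedges_g_worked_example():
    # d = 1, J = 1 - 3/71, vi = 20/100 + g^2/40
    yi, vi = hedges_g(2, 1, 10, 1, 1, 10)
    j = 1 - 3 / 71
    assert yi == pytest.approx(j)
    assert vi == pytest.approx(0.2 + j**2 / 40)


def test_hedges_g_identity_and_degenerate():
    yi, vi = hedges_g(3.0, 1.2, 9, 3.0, 1.2, 9)
    assert yi == 0.0 and vi == pytest.approx(18 / 81)
    # zero pooled SD: equal means -> 0; unequal -> undefined
    yi, vi = hedges_g(2.0, 0.0, 6, 2.0, 0.0, 6)
    assert yi == 0.0 and vi == pytest.approx(12 / 36)
    with pytest.raises(ValueError, match="undefined SMD"):
        hedges_g(2.0, 0.0, 6, 1.0, 0.0, 6)


@settings(max_examples=150, deadline=None)
@given(
    m1=st.floats(-50, 50), m2=st.floats(-50, 50),
    sd1=st.floats(0.1, 20), sd2=st.floats(0.1, 20),
    n1=st.integers(2, 200), n2=st.integers(2, 200),
)
def test_hedges_g_antisymmetry_and_variance_floor(m1, m2, sd1, sd2, n1, n2):
    yi, vi = hedges_g(m1, sd1, n1, m2, sd2, n2)
    yr, vr = hedges_g(m2, sd2, n2, m1, sd1, n1)
    assert yr == pytest.approx(-yi, abs=1e-12)
    assert vr == pytest.approx(vi, rel=1e-12)
    base = (n1 + n2) / (n1 * n2)
    assert vi >= base - 1e-15
    if yi == 0.0:
        assert vi == pytest.approx(base)


@pytest.mark.parametrize(
    "x,n,mean,sd",
    [
        (5, 10, 0.5, 0.5),
        (0, 10, 0.0, math.sqrt((0.5 / 11) * (1 - 0.5 / 11))),
        (10, 10, 1.0, math.sqrt((0.5 / 11) * (1 - 0.5 / 11))),
    ],
)
def test_binomial_sd(x, n, mean, sd):
    m, s = binomial_sd(x, n)
    assert m == pytest.approx(mean)
    assert s == pytest.approx(sd)
    assert s > 0


def test_binomial_sd_errors():
    with pytest.raises(ValueError):
        binomial_sd(1, 0)
    with pytest.raises(ValueError):
        binomial_sd(11, 10)


def test_build_comparisons_counts_and_signs(arm_table):
    eff = build_comparisons(arm_table)
    # 4 arms -> 4 comparisons; 2 arms -> 1 comparison
    assert len(eff) == 5
    s1 = eff.loc[eff["study_id"] == "s1"].set_index("comparison")
    assert set(s1.index) == {"night_vs_day", "day_vs_open", "night_vs_open", "open_vs_closed"}
    assert s1.loc["night_vs_day", "yi"] > 0          # night mean 12 > day mean 10
    assert s1.loc["day_vs_open", "yi"] < 0           # day 10 < open 14
    assert s1.loc["open_vs_closed", "yi"] > 0        # dependency positive
    s2 = eff.loc[eff["study_id"] == "s2", "yi"]
    assert (s2 < 0).all()                            # night 4 < day 5


def test_build_comparisons_errors(arm_table):
    dup = pd.concat([arm_table, arm_table.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        build_comparisons(dup)
    miss = arm_table.copy()
    miss.loc[0, "sd"] = np.nan
    with pytest.raises(ValueError, match="missing SD"):
        build_comparisons(miss)


def test_fruit_set_smd_matches_symbolic_oracle():
    """SMD computed from binomial (p, sqrt(p(1-p)), n) arms equals an exact
    rational/symbolic evaluation of the same formulas."""
    x1, n1, x2, n2 = 18, 30, 9, 24
    m1, s1 = binomial_sd(x1, n1)
    m2, s2 = binomial_sd(x2, n2)
    yi, vi = hedges_g(m1, s1, n1, m2, s2, n2)

    p1, p2 = sympy.Rational(x1, n1), sympy.Rational(x2, n2)
    sd1 = sympy.sqrt(p1 * (1 - p1))
    sd2 = sympy.sqrt(p2 * (1 - p2))
    sp = sympy.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    j = 1 - sympy.Rational(3, 4 * (n1 + n2 - 2) - 1)
    g = j * (p1 - p2) / sp
    v = sympy.Rational(n1 + n2, n1 * n2) + g**2 / (2 * (n1 + n2))
    assert yi == pytest.approx(float(g), rel=1e-12)
    assert vi == pytest.approx(float(v), rel=1e-12)


def test_filter_outliers_boundary_and_idempotence():
    eff = pd.DataFrame({"yi": [10.0, -12.3, 0.5, 10.0001, -10.0], "vi": [0.1] * 5})
    kept, removed = filter_outliers(eff)
    assert list(kept["yi"]) == [10.0, 0.5, -10.0]   # strict inequality, order kept
    assert list(removed["yi"]) == [-12.3, 10.0001]
    kept2, removed2 = filter_outliers(kept)
    pd.testing.assert_frame_equal(kept, kept2)
    assert removed2.empty
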