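"""REML engine unit tests: limits, identities, invariances and the
downstream inference helpers (QM, I^2, R^2, marginal means, BLUPs, BY)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielmeta.meta import (RandomEffect, blups, build_design, by_adjust, i2_multilevel,
                           marginal_means, marginal_r2, qm_test, reml_fit, reml_loglik,
                           species_predictions)
from tests.conftest import toy_meta_data


def test_fixed_effect_limit_equal_weights(rng):
    # no random components, equal vi -> intercept is the plain mean
    y = rng.normal(0.4, 1.0, 20)
    vi = np.full(20, 0.2)
    fit = reml_fit(y, vi, None, [])
    assert fit.beta[0] == pytest.approx(y.mean())
    assert fit.coef["se"].iloc[0] == pytest.approx(np.sqrt(0.2 / 20))


def test_engine_matches_dense_loglik(rng):
    y, vi, study, random = toy_meta_data(rng, k=40, n_study=8)
    X = np.column_stack([np.ones(40), rng.standard_normal(40)])
    fit = reml_fit(y, vi, X, random)
    # dense brute-force REML loglik at the estimated components
    s2 = np.array([fit.sigma2["study"], fit.sigma2["obs"]])
    Z = np.eye(8)[study]
    V = np.diag(vi) + s2[0] * Z @ Z.T + s2[1] * np.eye(40)
    Vi = np.linalg.inv(V)
    M = X.T @ Vi @ X
    beta = np.linalg.solve(M, X.T @ Vi @ y)
    r = y - X @ beta
    ll = -0.5 * ((40 - 2) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                 + np.linalg.slogdet(M)[1] + r @ Vi @ r
                 - np.linalg.slogdet(X.T @ X)[1])
    assert fit.loglik == pytest.approx(ll, abs=1e-8)
    assert np.allclose(fit.beta, beta, atol=1e-6)


def test_observation_reordering_invariance(rng):
    y, vi, study, _ = toy_meta_data(rng, k=50)
    x = rng.standard_normal(50)
    perm = rng.permutation(50)

    def fit_on(order):
        X = np.column_stack([np.ones(50), x[order]])
        rnd = [RandomEffect("study", study[order]), RandomEffect("obs", np.arange(50))]
        return reml_fit(y[order], vi[order], X, rnd)

    f1, f2 = fit_on(np.arange(50)), fit_on(perm)
    assert np.allclose(f1.beta, f2.beta, atol=1e-7)
    for name in f1.sigma2:
        assert f1.sigma2[name] == pytest.approx(f2.sigma2[name], abs=1e-7)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-7)


def test_component_order_invariance(rng):
    y, vi, study, _ = toy_meta_data(rng, k=50)
    r1 = [RandomEffect("study", study), RandomEffect("obs", np.arange(50))]
    r2 = [RandomEffect("obs", np.arange(50)), RandomEffect("study", study)]
    f1 = reml_fit(y, vi, None, r1)
    f2 = reml_fit(y, vi, None, r2)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-7)
    assert f1.sigma2["study"] == pytest.approx(f2.sigma2["study"], abs=1e-7)


def test_identity_phylo_merges_with_nonphylo(rng):
    """With the species correlation set to identity, phylogenetic and
    non-phylogenetic species effects are exchangeable: only their sum is
    identified and the fit must match a single merged component."""
    k = 60
    species = np.repeat([f"sp{i}" for i in range(12)], 5)
    y, vi, study, _ = toy_meta_data(rng, k=k)
    ident = pd.DataFrame(np.eye(12), index=[f"sp{i}" for i in range(12)],
                         columns=[f"sp{i}" for i in range(12)])
    split = reml_fit(y, vi, None, [
        RandomEffect("species_phylo", species, ident),
        RandomEffect("species_nonphylo", species),
        RandomEffect("obs", np.arange(k)),
    ])
    merged = reml_fit(y, vi, None, [
        RandomEffect("species", species),
        RandomEffect("obs", np.arange(k)),
    ])
    assert split.loglik == pytest.approx(merged.loglik, abs=1e-5)
    assert split.beta[0] == pytest.approx(merged.beta[0], abs=1e-6)
    total_split = split.sigma2["species_phylo"] + split.sigma2["species_nonphylo"]
    assert total_split == pytest.approx(merged.sigma2["species"], abs=1e-4)


def test_reml_fit_input_validation(rng):
    y = rng.normal(size=10)
    with pytest.raises(ValueError, match="vi"):
        reml_fit(y, np.zeros(10), None, [])
    with pytest.raises(ValueError, match="too few"):
        reml_fit(y[:3], np.full(3, 0.1), np.ones((3, 1)),
                 [RandomEffect("study", np.arange(3)), RandomEffect("obs", np.arange(3))])


def test_qm_single_column_equals_z_squared(rng):
    y, vi, study, random = toy_meta_data(rng, k=60)
    X = np.column_stack([np.ones(60), rng.standard_normal(60)])
    fit = reml_fit(y, vi, X, random, coef_names=["intercept", "x"])
    q, df, p = qm_test(fit, ["x"])
    assert df == 1
    assert q == pytest.approx(fit.coef["zval"].iloc[1] ** 2, rel=1e-10)
    assert p == pytest.approx(fit.coef["pval"].iloc[1], rel=1e-10)
    with pytest.raises(ValueError):
        qm_test(fit, [])


def test_i2_identities(rng):
    y, vi, study, random = toy_meta_data(rng, k=60)
    fit = reml_fit(y, vi, None, random)
    total, per = i2_multilevel(fit)
    assert total == pytest.approx(sum(per.values()), abs=1e-12)
    assert 0 <= total <= 1
    # classic reduction: equal vi = v, single component -> I2 = s2/(s2+v)
    v = 0.15
    vi_eq = np.full(60, v)
    fit1 = reml_fit(y, vi_eq, None, [RandomEffect("obs", np.arange(60))])
    total1, per1 = i2_multilevel(fit1)
    s2 = fit1.sigma2["obs"]
    assert total1 == pytest.approx(s2 / (s2 + v), rel=1e-10)
    with pytest.raises(ValueError):
        i2_multilevel(fit, vi=[0.1])


def test_i2_zero_when_no_heterogeneity(rng):
    # data with no excess dispersion: estimated sigma2 ~ 0 -> I2 ~ 0
    vi = np.full(80, 0.2)
    y = rng.normal(0.0, np.sqrt(0.2), 80)
    fit = reml_fit(y, vi, None, [RandomEffect("obs", np.arange(80))])
    total, _ = i2_multilevel(fit)
    assert total < 0.15


def test_marginal_r2_limits(rng):
    k = 120
    x = rng.standard_normal(k)
    vi = np.full(k, 0.05)
    random = [RandomEffect("obs", np.arange(k))]
    # null moderator -> R2 ~ 0
    y0 = rng.normal(0, np.sqrt(0.3 + 0.05), k)
    f0 = reml_fit(y0, vi, np.column_stack([np.ones(k), x]), random)
    assert marginal_r2(f0) < 0.05
    # strong moderator, no heterogeneity -> R2 ~ 1
    y1 = 2.0 * x + rng.normal(0, np.sqrt(0.05), k)
    f1 = reml_fit(y1, vi, np.column_stack([np.ones(k), x]), random)
    assert marginal_r2(f1) > 0.95
    fit_int = reml_fit(y0, vi, None, random)
    with pytest.raises(ValueError, match="intercept-only"):
        marginal_r2(fit_int)


def test_by_adjust_worked_example_and_properties():
    assert by_adjust([0.2])[0] == pytest.approx(0.2)
    adj = by_adjust([0.01, 0.02, 0.03])
    assert np.allclose(adj, [0.055, 0.055, 0.055], atol=1e-12)  # c(3) = 11/6
    with pytest.raises(ValueError):
        by_adjust([1.2])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_by_adjust_monotone_and_conservative(ps):
    ps = np.array(ps)
    adj = by_adjust(ps)
    assert np.all(adj >= ps - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in p-value rank


def test_marginal_means_symmetry(rng):
    # two levels with identical data -> identical marginal means
    k = 40
    lev = np.array(["a"] * 20 + ["b"] * 20)
    base = rng.normal(0.5, 0.4, 20)
    y = np.concatenate([base, base])
    vi = np.tile(rng.uniform(0.05, 0.2, 20), 2)
    quot = np.tile(rng.uniform(0.8, 1.4, 20), 2)
    df = pd.DataFrame({"lev": lev, "exposure_quotient": quot})
    X, names = build_design(df, "lev", "categorical")
    fit = reml_fit(y, vi, X, [RandomEffect("obs", np.arange(k))], coef_names=names)
    mm = marginal_means(fit, ["lev=a", "lev=b"])
    assert mm["estimate"].iloc[0] == pytest.approx(mm["estimate"].iloc[1], abs=1e-8)
    assert (mm["ci_lb"] <= mm["estimate"]).all() and (mm["estimate"] <= mm["ci_ub"]).all()
    with pytest.raises(ValueError):
        marginal_means(fit, ["lev=z"])


def test_species_predictions_zero_variance_collapses_to_fixed(rng):
    k = 60
    species = np.repeat([f"sp{i}" for i in range(6)], 10)
    ident = pd.DataFrame(np.eye(6), index=sorted(set(species)), columns=sorted(set(species)))
    vi = np.full(k, 0.1)
    y = rng.normal(0.3, np.sqrt(0.1), k)  # no species signal
    fit = reml_fit(y, vi, None, [
        RandomEffect("species_phylo", species, ident),
        RandomEffect("species_nonphylo", species),
        RandomEffect("obs", np.arange(k)),
    ])
    preds = species_predictions(fit)
    if fit.sigma2["species_phylo"] + fit.sigma2["species_nonphylo"] < 1e-8:
        assert np.allclose(preds["estimate"], fit.beta[0], atol=1e-8)
    assert (preds["ci_lb"] <= preds["estimate"]).all()
    assert (preds["estimate"] <= preds["ci_ub"]).all()


def test_blup_residual_identity(rng):
    """Exact decomposition: r = sum_k Z_k u_hat_k + vi * V^-1 r."""
    k = 60
    species = np.repeat([f"sp{i}" for i in range(6)], 10)
    y, vi, study, _ = toy_meta_data(rng, k=k)
    rnd = [RandomEffect("study", study),
           RandomEffect("species_nonphylo", species),
           RandomEffect("obs", np.arange(k))]
    fit = reml_fit(y, vi, None, rnd)
    r = y - fit._X @ fit.beta
    recon = vi * fit._Vir
    for comp in fit.sigma2:
        b = blups(fit, comp)
        lut = dict(zip(b["level"], b["blup"]))
        labels = {"study": study, "species_nonphylo": species, "obs": np.arange(k)}[comp]
        recon = recon + np.array([lut[l] for l in labels])
    assert np.allclose(recon, r, atol=1e-8)


def test_reml_loglik_standalone_matches_fit(rng):
    y, vi, study, random = toy_meta_data(rng, k=40, n_study=8)
    fit = reml_fit(y, vi, None, random)
    ll = reml_loglik([fit.sigma2["study"], fit.sigma2["obs"]], y, vi,
                     np.ones((40, 1)), random)
    assert ll == pytest.approx(fit.loglik, abs=1e-10)
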