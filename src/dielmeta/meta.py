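"""Multilevel meta-analytic models with known sampling variances.

Fits random-effects meta-analysis / meta-regression models of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k * A_k),  e ~ N(0, diag(vi))

by restricted maximum likelihood, where ``vi`` are the known per-effect
sampling variances of standardised mean differences and each random
component ``k`` has a grouping factor (study, outcome metric, species, or
the observation itself) and an optional correlation matrix ``A_k`` among
its levels (a phylogenetic correlation for the phylogenetic species
effect, identity otherwise).

The marginal covariance ``V = sum_k sigma2_k Z_k A_k Z_k' + diag(vi)`` is
never formed densely: components whose grouping factor has one level per
observation contribute to the diagonal, and every other component is a
rank-q_k term, so V is diagonal-plus-low-rank and all solves, log
determinants and likelihood gradients go through the Woodbury identity
and the matrix determinant lemma. This is exact (verified against dense
brute-force evaluation in the test suite), and it is what makes the
simulation-based calibration checks affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve, cholesky
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RandomEffect",
    "MetaFit",
    "reml_fit",
    "reml_loglik",
    "qm_test",
    "i2_multilevel",
    "marginal_r2",
    "marginal_means",
    "species_predictions",
    "blups",
    "by_adjust",
    "build_design",
]

_Z975 = 1.959963984540054


@dataclass
class RandomEffect:
    """One random component: a grouping factor plus optional level correlation.

    ``corr`` may be None (i.i.d. levels), a pandas DataFrame whose
    index/columns name the levels, or a ``(levels, matrix)`` pair.
    """

    name: str
    labels: np.ndarray
    corr: object | None = None


class _Component:
    """Compiled random component: codes into levels, and a Cholesky of A."""

    def __init__(self, re: RandomEffect, k: int):
        self.name = re.name
        labels = np.asarray(re.labels)
        if labels.shape[0] != k:
            raise ValueError(f"component {re.name!r}: {labels.shape[0]} labels for {k} observations")
        codes, levels = pd.factorize(labels)
        self.codes = codes
        self.levels = list(levels)
        q = len(levels)
        if re.corr is None:
            self.A = None
            # one level per observation -> pure diagonal contribution
            self.diagonal = q == k
            if not self.diagonal:
                self.L = np.eye(q)
        else:
            A, self.levels, self.codes = _align_corr(re.corr, labels)
            self.A = A
            self.diagonal = False
            self.L = _safe_cholesky(A)
        self.q = len(self.levels)

    def onehot(self) -> np.ndarray:
        Z = np.zeros((len(self.codes), self.q))
        Z[np.arange(len(self.codes)), self.codes] = 1.0
        return Z


def _align_corr(corr, labels):
    if isinstance(corr, pd.DataFrame):
        levels, mat = list(corr.index), corr.to_numpy(dtype=float)
        if list(corr.columns) != levels:
            raise ValueError("correlation matrix rows and columns must agree")
    else:
        levels, mat = corr
        levels = list(levels)
        mat = np.asarray(mat, dtype=float)
    lut = {lev: i for i, lev in enumerate(levels)}
    missing = sorted({str(l) for l in labels if l not in lut})
    if missing:
        raise ValueError(f"levels absent from correlation matrix: {missing}")
    used = sorted({lut[l] for l in labels})
    sub = mat[np.ix_(used, used)]
    sub_levels = [levels[i] for i in used]
    sub_lut = {lev: i for i, lev in enumerate(sub_levels)}
    codes = np.array([sub_lut[l] for l in labels])
    return sub, sub_levels, codes


def _safe_cholesky(A: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(6):
        try:
            return cholesky(A + jitter * np.eye(A.shape[0]), lower=True)
        except LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    raise LinAlgError("correlation matrix is not positive semi-definite")


class _VOp:
    """V = diag(d) + U~ U~' with U~ the sqrt(sigma2)-scaled low-rank blocks.

    Every block is Z_j T_j with Z_j a one-hot indicator, so all inner
    products reduce to grouped sums / weighted cross-tabulations followed
    by q x q dense algebra; nothing of size k x q is ever materialised.
    """

    def __init__(self, d: np.ndarray, blocks):
        self.d = d
        self.dinv = 1.0 / d
        self.blocks = blocks  # list of (component, sigma2 > 0)
        qs = [c.q for c, _ in blocks]
        self.q = int(np.sum(qs))
        self.slices = []
        off = 0
        for w in qs:
            self.slices.append(slice(off, off + w))
            off += w
        if self.q:
            self.W = self.wmat(self.dinv)
            K = np.eye(self.q) + self.W
            self.cK = cho_factor(K, lower=True)
            self.logdet = float(np.sum(np.log(d)) + 2.0 * np.sum(np.log(np.diag(self.cK[0]))))
        else:
            self.logdet = float(np.sum(np.log(d)))

    def _tmat(self, j):
        c, s2 = self.blocks[j]
        return np.sqrt(s2) * c.L if c.A is not None else None, np.sqrt(s2)

    def wmat(self, weights: np.ndarray) -> np.ndarray:
        """U~' diag(weights) U~ assembled blockwise."""
        W = np.zeros((self.q, self.q))
        for a, (ca, _) in enumerate(self.blocks):
            Ta, sa = self._tmat(a)
            for b in range(a, len(self.blocks)):
                cb, _ = self.blocks[b]
                Tb, sb = self._tmat(b)
                if a == b:
                    if Ta is None:
                        cross = np.diag(np.bincount(ca.codes, weights=weights, minlength=ca.q))
                    else:
                        w = np.bincount(ca.codes, weights=weights, minlength=ca.q)
                        cross = None
                        Wab = Ta.T @ (w[:, None] * Ta)
                        W[self.slices[a], self.slices[b]] = Wab
                        continue
                else:
                    cross = np.zeros((ca.q, cb.q))
                    np.add.at(cross, (ca.codes, cb.codes), weights)
                Wab = cross
                if Ta is not None:
                    Wab = Ta.T @ Wab
                else:
                    Wab = sa * Wab
                if Tb is not None:
                    Wab = Wab @ Tb
                else:
                    Wab = Wab * sb
                W[self.slices[a], self.slices[b]] = Wab
                if a != b:
                    W[self.slices[b], self.slices[a]] = Wab.T
        return W

    def ut(self, B: np.ndarray) -> np.ndarray:
        """U~' B via grouped sums; B is (k,) or (k, m)."""
        one_d = B.ndim == 1
        Bm = B[:, None] if one_d else B
        out = np.zeros((self.q, Bm.shape[1]))
        for j, (c, _) in enumerate(self.blocks):
            gs = np.zeros((c.q, Bm.shape[1]))
            np.add.at(gs, c.codes, Bm)
            Tj, sj = self._tmat(j)
            out[self.slices[j]] = (Tj.T @ gs) if Tj is not None else sj * gs
        return out[:, 0] if one_d else out

    def expand(self, C: np.ndarray) -> np.ndarray:
        """U~ C; C is (q,) or (q, m)."""
        one_d = C.ndim == 1
        Cm = C[:, None] if one_d else C
        k = len(self.d)
        out = np.zeros((k, Cm.shape[1]))
        for j, (c, _) in enumerate(self.blocks):
            Cj = Cm[self.slices[j]]
            Tj, sj = self._tmat(j)
            rows = (Tj @ Cj) if Tj is not None else sj * Cj
            out += rows[c.codes]
        return out[:, 0] if one_d else out

    def solve(self, B: np.ndarray) -> np.ndarray:
        db = B * (self.dinv[:, None] if B.ndim == 2 else self.dinv)
        if not self.q:
            return db
        t = cho_solve(self.cK, self.ut(db))
        corr = self.expand(t)
        return db - corr * (self.dinv[:, None] if B.ndim == 2 else self.dinv)

    def trace_inv(self) -> float:
        t = float(np.sum(self.dinv))
        if self.q:
            W2 = self.wmat(self.dinv**2)
            Kinv = cho_solve(self.cK, np.eye(self.q))
            t -= float(np.sum(Kinv * W2))
        return t


def _build_vop(sigma2, comps, vi):
    d = np.asarray(vi, dtype=float).copy()
    blocks = []
    for s2, c in zip(sigma2, comps):
        if c.diagonal:
            d = d + s2
        elif s2 > 0:
            blocks.append((c, float(s2)))
    return _VOp(d, blocks)


def _core(vop, X, y):
    ViX = vop.solve(X)
    Viy = vop.solve(y)
    M = X.T @ ViX
    cM = cho_factor(M, lower=True)
    beta = cho_solve(cM, X.T @ Viy)
    Vir = Viy - ViX @ beta
    quad = float((y - X @ beta) @ Vir)
    logdetM = float(2.0 * np.sum(np.log(np.diag(cM[0]))))
    return ViX, Viy, M, cM, beta, Vir, quad, logdetM


def _loglik_from_parts(k, p, vop, quad, logdetM, method, logdetXtX=0.0):
    # the + 1/2 log|X'X| term is a constant in the variance components,
    # included so REML logliks match the usual meta-analytic convention
    if method == "REML":
        return -0.5 * ((k - p) * np.log(2 * np.pi) + vop.logdet + logdetM + quad - logdetXtX)
    return -0.5 * (k * np.log(2 * np.pi) + vop.logdet + quad)


def reml_loglik(sigma2, y, vi, X, random: Sequence[RandomEffect], method: str = "REML") -> float:
    """Restricted (or profile ML) log-likelihood at fixed variance components."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, p = X.shape
    comps = [_Component(re, k) for re in random]
    vop = _build_vop(np.asarray(sigma2, dtype=float), comps, vi)
    _, _, _, _, _, _, quad, logdetM = _core(vop, X, y)
    ldx = float(np.linalg.slogdet(X.T @ X)[1])
    return float(_loglik_from_parts(k, p, vop, quad, logdetM, method, ldx))


def _nll_grad(log_s2, comps, vi, X, y, method):
    """Negative REML/ML log-likelihood and its gradient on the log-variance
    scale: d(-ll)/d log s2_j = s2_j/2 [tr(P C_j) - (Py)' C_j (Py)].

    For low-rank components the sigma2_j factor is absorbed by working
    with the scaled blocks U~_j = sqrt(s2_j) Z_j T_j: the traces and
    quadratic forms below already carry it.
    """
    s2 = np.exp(log_s2)
    k, p = X.shape
    vop = _build_vop(s2, comps, vi)
    ViX, Viy, M, cM, beta, Vir, quad, logdetM = _core(vop, X, y)
    ll = _loglik_from_parts(k, p, vop, quad, logdetM, method)

    if vop.q:
        Kinv = cho_solve(vop.cK, np.eye(vop.q))
        ut_Py = vop.ut(Vir)            # U~' P y (X' V^-1 r = 0, so Py = V^-1 r)
        ut_ViX = vop.ut(ViX)           # U~' V^-1 X
    block_of = {id(c): j for j, (c, _) in enumerate(vop.blocks)}

    grad = np.zeros_like(s2)
    for j, c in enumerate(comps):
        if c.diagonal:
            tr = vop.trace_inv()
            qterm = float(Vir @ Vir)
            if method == "REML":
                tr -= float(np.trace(cho_solve(cM, ViX.T @ ViX)))
            grad[j] = 0.5 * (tr - qterm) * s2[j]
        else:
            b = block_of.get(id(c))
            if b is None:  # sigma2 underflowed to 0; gradient of the scaled block is 0
                grad[j] = 0.0
                continue
            rows = vop.slices[b]
            Wj = vop.W[rows, :]
            tr = float(np.trace(vop.W[rows, rows])) - float(np.sum(Wj * (Wj @ Kinv)))
            if method == "REML":
                Aj = ut_ViX[rows]      # q_j x p = U~_j' V^-1 X
                tr -= float(np.sum(Aj.T * cho_solve(cM, Aj.T)))
            qterm = float(np.sum(ut_Py[rows] ** 2))
            grad[j] = 0.5 * (tr - qterm)
    return -ll, grad


@dataclass
class MetaFit:
    """Result of one REML (or ML) multilevel meta-analytic fit."""

    coef: pd.DataFrame
    sigma2: dict
    loglik: float
    method: str
    k: int
    p: int
    QE: tuple
    QM: tuple
    coef_names: list = field(default_factory=list)
    # internal state for downstream inference (BLUPs, marginal means, ...)
    _X: np.ndarray = None
    _y: np.ndarray = None
    _vi: np.ndarray = None
    _comps: list = None
    _vop: object = None
    _ViX: np.ndarray = None
    _Vir: np.ndarray = None
    _cM: object = None
    _M: np.ndarray = None

    @property
    def beta(self) -> np.ndarray:
        return self.coef["estimate"].to_numpy()

    def cov_beta(self) -> np.ndarray:
        return cho_solve(self._cM, np.eye(self.p))


def reml_fit(
    y,
    vi,
    X=None,
    random: Sequence[RandomEffect] = (),
    coef_names=None,
    method: str = "REML",
    qm_cols=None,
) -> MetaFit:
    """Fit a multilevel meta-analytic model by (restricted) maximum likelihood.

    Parameters
    ----------
    y, vi : arrays of effect sizes and their known sampling variances.
    X : fixed-effect design matrix (defaults to an intercept).
    random : sequence of :class:`RandomEffect`.
    qm_cols : columns for the omnibus moderator test (default: all
        non-constant columns).
    """
    y = np.asarray(y, dtype=float)
    vi = np.asarray(vi, dtype=float)
    if np.any(vi <= 0):
        raise ValueError("all sampling variances vi must be > 0")
    if X is None:
        X = np.ones((y.shape[0], 1))
        coef_names = coef_names or ["intercept"]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, p = X.shape
    if coef_names is None:
        coef_names = [f"b{i}" for i in range(p)]
    m = len(random)
    if k <= p + m:
        raise ValueError(f"too few effect sizes (k={k}) for p={p} coefficients and {m} components")
    comps = [_Component(re, k) for re in random]
    ldx = float(np.linalg.slogdet(X.T @ X)[1])

    if m == 0:
        s2_hat = np.array([])
        vop = _build_vop(s2_hat, comps, vi)
        ViX, Viy, M, cM, beta, Vir, quad, logdetM = _core(vop, X, y)
        ll = _loglik_from_parts(k, p, vop, quad, logdetM, method, ldx)
    else:
        tau0 = max(float(np.var(y, ddof=1) - np.mean(vi)), 0.05 * float(np.mean(vi)))
        base = np.full(m, max(tau0 / m, 1e-4))
        starts = [base, base * 10.0, base * 0.1]
        bounds = [(np.log(1e-12), np.log(1e8))] * m
        best, prev_fun = None, None
        for s0 in starts:
            res = optimize.minimize(
                _nll_grad,
                np.log(s0),
                args=(comps, vi, X, y, method),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            # surface is usually unimodal here: once two starts agree, stop
            if prev_fun is not None and np.isfinite(res.fun) and abs(res.fun - prev_fun) < 1e-8:
                break
            prev_fun = res.fun
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("REML optimisation failed: non-finite likelihood")
        s2_hat = np.exp(best.x)
        s2_hat[s2_hat < 1e-10] = 0.0
        vop = _build_vop(s2_hat, comps, vi)
        ViX, Viy, M, cM, beta, Vir, quad, logdetM = _core(vop, X, y)
        ll = _loglik_from_parts(k, p, vop, quad, logdetM, method, ldx)

    covb = cho_solve(cM, np.eye(p))
    se = np.sqrt(np.diag(covb))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame(
        {
            "name": coef_names,
            "estimate": beta,
            "se": se,
            "zval": z,
            "pval": pvals,
            "ci_lb": beta - _Z975 * se,
            "ci_ub": beta + _Z975 * se,
        }
    )

    # QE: residual heterogeneity of the fixed-effects (vi-weighted) model
    w = 1.0 / vi
    Xw = X * w[:, None]
    beta_w = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    qe_stat = float(np.sum(w * (y - X @ beta_w) ** 2))
    qe_df = k - p
    QE = (qe_stat, qe_df, float(stats.chi2.sf(qe_stat, qe_df)))

    fit = MetaFit(
        coef=coef,
        sigma2={re.name: float(s2) for re, s2 in zip(random, s2_hat)},
        loglik=float(ll),
        method=method,
        k=k,
        p=p,
        QE=QE,
        QM=(np.nan, 0, np.nan),
        coef_names=list(coef_names),
        _X=X,
        _y=y,
        _vi=vi,
        _comps=comps,
        _vop=vop,
        _ViX=ViX,
        _Vir=Vir,
        _cM=cM,
        _M=M,
    )
    if qm_cols is None:
        const = [i for i in range(p) if np.ptp(X[:, i]) == 0]
        qm_cols = [i for i in range(p) if i not in const]
    if qm_cols:
        fit.QM = qm_test(fit, qm_cols)
    return fit


def qm_test(fit: MetaFit, which) -> tuple:
    """Omnibus Wald chi-square test of a set of model coefficients.

    ``which`` may hold column indices or coefficient names. Returns
    ``(Q, df, p)``.
    """
    idx = [fit.coef_names.index(w) if isinstance(w, str) else int(w) for w in which]
    if not idx:
        raise ValueError("no coefficients selected")
    covb = fit.cov_beta()
    b = fit.beta[idx]
    sub = covb[np.ix_(idx, idx)]
    try:
        q = float(b @ np.linalg.solve(sub, b))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular coefficient covariance in QM test") from err
    df = len(idx)
    return (q, df, float(stats.chi2.sf(q, df)))


def i2_multilevel(fit: MetaFit, vi=None) -> tuple[float, dict]:
    """Multilevel I^2: share of total variance due to each random component.

    Uses the typical (study-size-weighted) sampling variance
    ``vtilde = (k-1) sum(w) / (sum(w)^2 - sum(w^2))`` with ``w = 1/vi``.
    Returns ``(total, per_component)`` on the [0, 1] scale; the
    per-component values sum to the total by construction.
    """
    vi = fit._vi if vi is None else np.asarray(vi, dtype=float)
    k = len(vi)
    if k < 2:
        raise ValueError("I^2 requires at least 2 effect sizes")
    w = 1.0 / vi
    vtilde = (k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
    denom = sum(fit.sigma2.values()) + vtilde
    per = {name: s2 / denom for name, s2 in fit.sigma2.items()}
    return float(sum(per.values())), per


def marginal_r2(fit: MetaFit) -> float:
    """Marginal R^2: fixed-effect variance over fixed + random variance."""
    if fit.p < 2:
        raise ValueError("marginal R^2 undefined for an intercept-only model")
    f = fit._X @ fit.beta
    var_f = float(np.var(f, ddof=1))
    r2 = var_f / (var_f + sum(fit.sigma2.values()))
    return float(min(max(r2, 0.0), 1.0))


def marginal_means(fit: MetaFit, level_cols: Sequence[str], at: dict | None = None) -> pd.DataFrame:
    """Marginal mean and 95% CI per level of a cell-means-coded factor.

    Every non-factor column (e.g. the diel exposure quotient) is held at
    its observed mean unless overridden through ``at``.
    """
    base = fit._X.mean(axis=0)
    covb = fit.cov_beta()
    rows = []
    for lev in level_cols:
        if lev not in fit.coef_names:
            raise ValueError(f"level column {lev!r} not in the model")
        L = base.copy()
        for other in level_cols:
            L[fit.coef_names.index(other)] = 0.0
        L[fit.coef_names.index(lev)] = 1.0
        if at:
            for name, val in at.items():
                L[fit.coef_names.index(name)] = val
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ covb @ L))
        rows.append({"level": lev, "estimate": est, "se": se,
                     "ci_lb": est - _Z975 * se, "ci_ub": est + _Z975 * se})
    return pd.DataFrame(rows)


def blups(fit: MetaFit, component: str) -> pd.DataFrame:
    """Empirical BLUPs u_hat = sigma2 A Z' V^-1 (y - X beta_hat) for one component."""
    comp = _get_comp(fit, component)
    s2 = fit.sigma2[component]
    agg = np.zeros(comp.q)
    np.add.at(agg, comp.codes, fit._Vir)
    u = s2 * (comp.A @ agg if comp.A is not None else agg)
    return pd.DataFrame({"level": comp.levels, "blup": u})


def _get_comp(fit: MetaFit, name: str):
    for c in fit._comps:
        if c.name == name:
            return c
    raise KeyError(f"no random component named {name!r}")


def species_predictions(
    fit: MetaFit,
    phylo: str = "species_phylo",
    nonphylo: str = "species_nonphylo",
) -> pd.DataFrame:
    """Marginal species-level predictions: fixed prediction + species BLUPs.

    The estimate for species s is ``l'beta + u_phylo[s] + u_nonphylo[s]``
    with l the observed design mean (so the exposure quotient is held at
    its mean), and the SE is the conditional prediction-error variance of
    the combined quantity, accounting for the estimation of beta.
    """
    cp = _get_comp(fit, phylo)
    cn = _get_comp(fit, nonphylo)
    s2p, s2n = fit.sigma2[phylo], fit.sigma2[nonphylo]
    species = cp.levels
    S = cp.q
    lut = {lev: i for i, lev in enumerate(species)}
    try:
        remap = np.array([lut[lev] for lev in cn.levels])
    except KeyError as err:
        raise ValueError("non-phylogenetic species levels must match the phylogenetic ones") from err

    k = fit.k
    # cov(t_s, y_i) for the target t_s = u_phylo[s] + u_nonphylo[s]
    C = s2p * cp.A[cp.codes, :]
    C[np.arange(k), remap[cn.codes]] += s2n
    t_hat = C.T @ fit._Vir
    G = fit._vop.solve(C)
    cVc = np.sum(C * G, axis=0)
    XtG = fit._X.T @ G  # p x S
    l = fit._X.mean(axis=0)
    H = l[:, None] - XtG
    var_fix = np.sum(H * cho_solve(fit._cM, H), axis=0)
    predvar = np.maximum((s2p + s2n) - cVc + var_fix, 0.0)
    est = float(l @ fit.beta) + t_hat
    se = np.sqrt(predvar)
    out = pd.DataFrame(
        {
            "species": species,
            "estimate": est,
            "se": se,
            "ci_lb": est - _Z975 * se,
            "ci_ub": est + _Z975 * se,
        }
    )
    out["excludes_zero"] = (out["ci_lb"] > 0) | (out["ci_ub"] < 0)
    return out


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def build_design(
    df: pd.DataFrame,
    moderator: str | None = None,
    kind: str = "none",
    quadratic: bool = False,
    quotient_col: str = "exposure_quotient",
):
    """Design matrix builder for the standard single-moderator models.

    ``kind``: "none" (intercept + quotient), "continuous" (intercept +
    moderator [+ moderator^2] + quotient) or "categorical" (cell-means
    coding per level + quotient). Returns ``(X, names)``.
    """
    n = len(df)
    quot = df[quotient_col].to_numpy(dtype=float) if quotient_col in df else np.ones(n)
    if kind == "none" or moderator is None:
        X = np.column_stack([np.ones(n), quot])
        return X, ["intercept", "quotient"]
    if kind == "continuous":
        x = df[moderator].to_numpy(dtype=float)
        cols, names = [np.ones(n), x], ["intercept", moderator]
        if quadratic:
            cols.append(x**2)
            names.append(f"{moderator}^2")
        cols.append(quot)
        names.append("quotient")
        return np.column_stack(cols), names
    if kind == "categorical":
        codes, levels = pd.factorize(df[moderator])
        X = np.zeros((n, len(levels) + 1))
        X[np.arange(n), codes] = 1.0
        X[:, -1] = quot
        names = [f"{moderator}={lev}" for lev in levels] + ["quotient"]
        return X, names
    raise ValueError(f"unknown design kind {kind!r}")
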