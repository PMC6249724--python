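"""Lightweight fitters for the association grids.

Two model families recur hundreds of times per analysis run: Gaussian linear
mixed models with a single random intercept (individual identity) and
Poisson/logistic GLMs.  Both are fitted here directly -- the LMM by REML with
the variance ratio profiled out (Brent search on the one remaining parameter),
the GLMs by Newton/IRLS -- so that a full grid of ~1000 fits runs in about a
second.  Results agree with statsmodels MixedLM / GLM to numerical precision
(see the cross-check tests).

Notation: y = X beta + b_g + eps with b_g ~ N(0, sigma2_b) per group g and
eps ~ N(0, sigma2_e); lam = sigma2_b / sigma2_e is the profiled ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMFit", "GLMFit", "fit_random_intercept_lmm", "fit_glm"]


@dataclass
class LMMFit:
    """REML fit of a random-intercept linear mixed model."""

    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    df: np.ndarray          # Satterthwaite-style df per coefficient
    pvalues: np.ndarray
    sigma2_e: float
    sigma2_b: float
    lam: float
    reml_criterion: float   # -2 * restricted log-likelihood (constants dropped)
    n: int
    rank: int
    n_groups: int
    singleton: bool         # True when every group has a single observation
    degenerate: bool = False
    note: str = ""

    @property
    def icc(self) -> float:
        tot = self.sigma2_b + self.sigma2_e
        return 0.0 if tot <= 0 else float(np.clip(self.sigma2_b / tot, 0.0, 1.0))


@dataclass
class GLMFit:
    """Newton/IRLS fit of a Poisson (log) or binomial (logit) GLM."""

    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    family: str
    n: int
    converged: bool
    separated: bool = False
    dispersion: float = 1.0
    df_resid: float | None = None     # t reference df when dispersion-scaled
    note: str = ""


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (sorting order, reduceat start offsets) for group aggregation."""
    order = np.argsort(groups, kind="stable")
    sorted_g = groups[order]
    starts = np.flatnonzero(np.r_[True, sorted_g[1:] != sorted_g[:-1]])
    return order, starts


def _reml_pieces(lam, y, X, gsizes, starts, XtX, Xty, yty):
    """GLS cross-products and log-determinants for a given variance ratio."""
    c = lam / (1.0 + lam * gsizes)                       # per-group shrinkage
    Sx = np.add.reduceat(X, starts, axis=0)              # group column sums
    Sy = np.add.reduceat(y, starts)
    XtSX = XtX - (Sx * c[:, None]).T @ Sx
    XtSy = Xty - (Sx * (c * Sy)[:, None]).sum(axis=0)
    ytSy = yty - float(c @ Sy**2)
    logdet_sigma = float(np.sum(np.log1p(lam * gsizes)))
    return XtSX, XtSy, ytSy, logdet_sigma


def _reml_criterion(lam, y, X, gsizes, starts, XtX, Xty, yty, n, p):
    XtSX, XtSy, ytSy, logdet_sigma = _reml_pieces(
        lam, y, X, gsizes, starts, XtX, Xty, yty
    )
    try:
        L = np.linalg.cholesky(XtSX)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(XtSX, XtSy)
    rss = max(ytSy - float(XtSy @ beta), 1e-300)
    sigma2 = rss / (n - p)
    logdet_xsx = 2.0 * float(np.sum(np.log(np.diag(L))))
    return (n - p) * np.log(sigma2) + logdet_sigma + logdet_xsx


def _criterion_at(s, loglam, y, X, gsizes, starts, XtX, Xty, yty, n, p):
    """Unprofiled -2 restricted log-likelihood at (log sigma2_e, log lam)."""
    lam = np.exp(loglam)
    sigma2 = np.exp(s)
    XtSX, XtSy, ytSy, logdet_sigma = _reml_pieces(
        lam, y, X, gsizes, starts, XtX, Xty, yty
    )
    beta = np.linalg.solve(XtSX, XtSy)
    rss = max(ytSy - float(XtSy @ beta), 0.0)
    sign, logdet_xsx = np.linalg.slogdet(XtSX)
    return rss / sigma2 + (n - p) * s + logdet_sigma + logdet_xsx


def _satterthwaite_df(s_hat, loglam_hat, var_beta_fn, crit_fn, n, p):
    """Per-coefficient Satterthwaite df from finite-difference curvature.

    df_j = 2 g_j^2 / (grad_j' Cov grad_j) with g_j = Var(beta_j) as a function
    of theta = (log sigma2_e, log lam) and Cov(theta) = 2 H^{-1}, H the
    Hessian of the -2 restricted log-likelihood.
    """
    h = 1e-4
    theta = np.array([s_hat, loglam_hat])

    def g(th):
        return var_beta_fn(th[0], th[1])

    g0 = g(theta)
    grads = np.empty((2, g0.size))
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        grads[k] = (g(tp) - g(tm)) / (2 * h)

    H = np.empty((2, 2))
    f0 = crit_fn(*theta)
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        H[k, k] = (crit_fn(*tp) - 2 * f0 + crit_fn(*tm)) / h**2
    H[0, 1] = H[1, 0] = (
        crit_fn(*(theta + np.array([h, h])))
        - crit_fn(*(theta + np.array([h, -h])))
        - crit_fn(*(theta + np.array([-h, h])))
        + crit_fn(*(theta + np.array([-h, -h])))
    ) / (4 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(H)
        denom = np.einsum("kj,kl,lj->j", grads, cov, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * g0**2 / denom
        df = np.where(np.isfinite(df) & (df > 0), df, n - p)
    except np.linalg.LinAlgError:
        df = np.full(g0.size, n - p, dtype=float)
    return np.clip(df, 1.0, n - p)


def fit_random_intercept_lmm(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> LMMFit:
    """Fit y = X beta + b_group + eps by REML.

    Falls back to OLS (with a note) when no group has a repeat observation,
    in which case the random intercept variance is not estimable.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (constant or collinear column)")

    order, starts = _group_index(groups)
    ys, Xs = y[order], X[order]
    gsizes = np.diff(np.r_[starts, n]).astype(float)
    n_groups = len(starts)
    singleton = bool(gsizes.max() == 1)

    XtX, Xty, yty = Xs.T @ Xs, Xs.T @ ys, float(ys @ ys)

    if singleton:
        beta = np.linalg.solve(XtX, Xty)
        rss = max(yty - float(Xty @ beta), 1e-300)
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov))
        t = beta / se
        df = np.full(p, n - p, dtype=float)
        pv = 2 * stats.t.sf(np.abs(t), df)
        crit = (n - p) * np.log(sigma2) + np.linalg.slogdet(XtX)[1]
        return LMMFit(beta, se, t, df, pv, sigma2, 0.0, 0.0, crit, n, p,
                      n_groups, True, note="random intercept dropped: all groups singleton")

    args = (ys, Xs, gsizes, starts, XtX, Xty, yty, n, p)

    def obj(loglam):
        return _reml_criterion(np.exp(loglam), *args)

    res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-6})
    crit_hat = res.fun
    lam = float(np.exp(res.x))
    crit0 = _reml_criterion(0.0, *args)
    boundary = crit0 <= crit_hat + 1e-10
    if boundary:
        lam, crit_hat = 0.0, crit0

    XtSX, XtSy, ytSy, _ = _reml_pieces(lam, ys, Xs, gsizes, starts, XtX, Xty, yty)
    beta = np.linalg.solve(XtSX, XtSy)
    rss = max(ytSy - float(XtSy @ beta), 1e-300)
    sigma2_e = rss / (n - p)
    sigma2_b = lam * sigma2_e
    cov = sigma2_e * np.linalg.inv(XtSX)
    se = np.sqrt(np.diag(cov))
    t = beta / se

    if boundary or lam < 1e-8:
        df = np.full(p, n - p, dtype=float)
    else:
        def var_beta(s, loglam):
            pieces = _reml_pieces(np.exp(loglam), ys, Xs, gsizes, starts, XtX, Xty, yty)
            return np.exp(s) * np.diag(np.linalg.inv(pieces[0]))

        def crit_fn(s, loglam):
            return _criterion_at(s, loglam, *args)

        df = _satterthwaite_df(np.log(sigma2_e), np.log(lam), var_beta, crit_fn, n, p)

    pv = 2 * stats.t.sf(np.abs(t), df)
    return LMMFit(beta, se, t, df, pv, float(sigma2_e), float(sigma2_b),
                  lam, float(crit_hat), n, p, n_groups, False,
                  note="random-intercept variance at boundary (0)" if boundary else "")


def reml_criterion_at_lambda(y, X, groups, lam: float) -> float:
    """-2 restricted log-likelihood (constants dropped) at a fixed ratio.

    Used for boundary likelihood-ratio tests of the random-intercept variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    order, starts = _group_index(np.asarray(groups))
    ys, Xs = y[order], X[order]
    gsizes = np.diff(np.r_[starts, n]).astype(float)
    return _reml_criterion(lam, ys, Xs, gsizes, starts, Xs.T @ Xs, Xs.T @ ys,
                           float(ys @ ys), n, p)


_FAMILIES = ("poisson", "binomial")


def fit_glm(
    y: np.ndarray,
    X: np.ndarray,
    family: str,
    quasi: bool = False,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> GLMFit:
    """Newton/IRLS fit of a canonical-link GLM.

    With ``quasi=True`` (quasi-likelihood), the covariance is scaled by the
    Pearson dispersion (floored at 1) and p-values use a t reference with
    n - p df -- the standard remedy for mildly overdispersed counts that
    avoids the small-sample anticonservatism of sandwich estimators.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (constant or collinear column)")

    beta = np.zeros(p)
    if family == "poisson":
        beta[0] = np.log(max(y.mean(), 1e-8))
    else:
        mu0 = np.clip(y.mean(), 1e-4, 1 - 1e-4)
        beta[0] = np.log(mu0 / (1 - mu0))

    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        if family == "poisson":
            mu = np.exp(eta)
            w = mu
        else:
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = np.clip(X @ beta, -30, 30)
    if family == "poisson":
        mu = np.exp(eta)
        w = mu
    else:
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)

    separated = family == "binomial" and (not converged or np.max(np.abs(beta)) > 15)

    dispersion = 1.0
    df_resid = None
    if quasi and n > p:
        with np.errstate(divide="ignore", invalid="ignore"):
            pearson = np.where(w > 0, (y - mu) ** 2 / np.maximum(w, 1e-300), 0.0)
        dispersion = max(float(pearson.sum() / (n - p)), 1.0)
        cov = dispersion * cov
        df_resid = float(n - p)

    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    if df_resid is not None:
        pv = 2 * stats.t.sf(np.abs(z), df_resid)
    else:
        pv = 2 * stats.norm.sf(np.abs(z))
    return GLMFit(beta, se, z, pv, family, n, converged, separated,
                  dispersion, df_resid)
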