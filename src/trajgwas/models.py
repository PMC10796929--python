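"""Marginal and mixed models for repeated cognitive measures.

The workhorse is a Gaussian generalised-estimating-equation (GEE) solver
with identity link. GEE treats the within-subject correlation of repeated
measures as a nuisance: a *working* correlation structure is assumed, the
regression coefficients are estimated by iteratively re-weighted least
squares, and the sandwich (robust) covariance ``A^-1 B A^-1`` protects the
standard errors against misspecification of that structure. The solver is
written directly against per-cluster sufficient statistics so that a
genome-wide scan (one fit per variant) stays cheap: for independence and
exchangeable working correlations every quantity reduces to grouped sums
over clusters, computed with ``np.add.reduceat`` over a cluster-sorted
design, and the exchangeable inverse uses the Sherman-Morrison identity

    R^-1 = [I - a/(1+(n-1)a) J] / (1-a)

so no per-cluster matrix is ever materialised. The unstructured working
correlation (all visit-pair correlations free) is also available for
cohorts measured on a shared visit grid; it loops over clusters and is
meant for single model fits, not scans.

A REML linear mixed model (random intercept + slope) is provided for model
exploration and polygenic-score testing; it wraps statsmodels' MixedLM and
re-expresses its output as variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GEEFit",
    "LMMFit",
    "fit_gee",
    "fit_lmm_reml",
    "wald_test",
]


@dataclass
class GEEFit:
    """Result of one GEE fit.

    ``beta`` solves the estimating equation under the working correlation;
    ``naive_cov`` is the model-based covariance ``phi * A^-1`` and
    ``robust_cov`` the sandwich ``A^-1 B A^-1`` (valid even when the
    working correlation is wrong). ``corr_params`` holds the moment
    estimate of the working-correlation parameter(s): a scalar alpha for
    exchangeable, a visit-by-visit matrix for unstructured, empty for
    independence.
    """

    beta: np.ndarray
    naive_cov: np.ndarray
    robust_cov: np.ndarray
    corr_params: object
    dispersion: float
    n_clusters: int
    n_obs: int
    n_iter: int
    converged: bool
    exog_names: list[str] = field(default_factory=list)

    @property
    def naive_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_cov))

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    def wald(self):
        """Robust z statistics and two-sided normal p-values per coefficient."""
        z = self.beta / self.robust_se
        return z, 2.0 * stats.norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        z, p = self.wald()
        return {
            "beta": dict(zip(self.exog_names, self.beta.tolist())),
            "robust_se": dict(zip(self.exog_names, self.robust_se.tolist())),
            "p": dict(zip(self.exog_names, p.tolist())),
            "dispersion": self.dispersion,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass
class LMMFit:
    """REML mixed-model fit: fixed effects plus variance components."""

    beta: np.ndarray
    cov_beta: np.ndarray
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    var_resid: float
    reml_loglike: float
    converged: bool
    random_slope: bool
    exog_names: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def wald(self):
        z = self.beta / self.se
        return z, 2.0 * stats.norm.sf(np.abs(z))


def wald_test(beta: float, se: float):
    """Two-sided Wald test of H0: beta = 0 against a normal reference.

    Returns ``(z, p)`` with ``p = 2 * Phi(-|z|)``. Raises on ``se <= 0``.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = beta / se
    return z, 2.0 * stats.norm.sf(abs(z))


# ---------------------------------------------------------------------------
# GEE core


def _cluster_layout(groups: np.ndarray):
    """Stable-sort row order plus reduceat boundaries for each cluster."""
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    sizes = np.diff(np.r_[starts, len(sorted_groups)])
    return order, starts, sizes


def _exchangeable_products(X, y, e, starts, sizes, alpha):
    """Per-cluster GEE building blocks under exchangeable R via Sherman-Morrison.

    Returns (XtRiX, XtRiy, U) where U stacks per-cluster scores X_i' R_i^-1 e_i.
    """
    one_m = 1.0 - alpha
    k = alpha / (1.0 + (sizes - 1.0) * alpha)  # per cluster
    S = np.add.reduceat(X, starts, axis=0)  # cluster column sums of X
    ysum = np.add.reduceat(y, starts)
    esum = np.add.reduceat(e, starts)
    XtRiX = (X.T @ X - (S.T * k) @ S) / one_m
    XtRiy = (X.T @ y - S.T @ (k * ysum)) / one_m
    T = np.add.reduceat(X * e[:, None], starts, axis=0)
    U = (T - (k * esum)[:, None] * S) / one_m
    return XtRiX, XtRiy, U


def _unstructured_R(e, starts, sizes, visit, n_visits, phi):
    """Moment estimate of the visit-by-visit working correlation."""
    r = e / np.sqrt(phi)
    num = np.zeros((n_visits, n_visits))
    cnt = np.zeros((n_visits, n_visits))
    for s, n in zip(starts, sizes):
        v = visit[s : s + n]
        ri = r[s : s + n]
        num[np.ix_(v, v)] += np.outer(ri, ri)
        cnt[np.ix_(v, v)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(cnt > 0, num / np.maximum(cnt, 1.0), 0.0)
    np.fill_diagonal(R, 1.0)
    # project to a usable correlation matrix if moments stray outside [-1, 1]
    R = np.clip(R, -0.99, 1.0)
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-6:
        R = V @ np.diag(np.maximum(w, 1e-6)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def _exchangeable_Rinv(s: int, alpha: float) -> np.ndarray:
    """Closed-form inverse of the s x s exchangeable correlation matrix."""
    I = np.eye(s)
    if s == 1:
        return I
    J = np.ones((s, s))
    return (I - (alpha / (1.0 + (s - 1.0) * alpha)) * J) / (1.0 - alpha)


def _mancl_derouen_B(X, e, starts, sizes, A_inv, working_correlation, alpha, R, visit):
    """Bias-corrected empirical middle matrix of the sandwich.

    Per cluster the residuals are inflated by (I - H_i)^-1 with
    H_i = X_i A^-1 X_i' R_i^-1 before forming the score outer products
    (Mancl & DeRouen's correction for the downward small-sample bias of
    the uncorrected sandwich). Clusters are processed in batches of equal
    size so the correction stays cheap inside a genome-wide scan.
    """
    p = X.shape[1]
    B = np.zeros((p, p))
    if working_correlation == "unstructured":
        for s0, n in zip(starts, sizes):
            v = visit[s0 : s0 + n]
            Rinv = np.linalg.inv(R[np.ix_(v, v)])
            Xi = X[s0 : s0 + n]
            Q = Rinv @ Xi  # (n, p)
            H = Xi @ A_inv @ Q.T
            et = np.linalg.solve(np.eye(n) - H, e[s0 : s0 + n])
            u = Q.T @ et
            B += np.outer(u, u)
        return B
    for s in np.unique(sizes):
        sel = np.flatnonzero(sizes == s)
        rows = starts[sel][:, None] + np.arange(s)[None, :]
        Xb = X[rows]  # (nc, s, p)
        eb = e[rows]  # (nc, s)
        Rinv = np.eye(s) if working_correlation == "independence" else _exchangeable_Rinv(s, alpha)
        Q = np.matmul(Rinv, Xb)  # R_i^-1 X_i, batched: (nc, s, p)
        M = Xb @ A_inv  # (nc, s, p)
        H = M @ Q.transpose(0, 2, 1)  # (nc, s, s)
        et = np.linalg.solve(np.eye(s)[None] - H, eb[..., None])[..., 0]
        U = np.einsum("nsp,ns->np", Q, et)
        B += U.T @ U
    return B


def fit_gee(
    y,
    X,
    groups,
    working_correlation: str = "exchangeable",
    max_iter: int = 50,
    tol: float = 1e-8,
    exog_names=None,
    visit_index=None,
    bias_correction: str | None = None,
    _layout=None,
) -> GEEFit:
    """Fit a Gaussian identity-link GEE.

    Parameters
    ----------
    y, X
        Response vector and full-rank design matrix (n_obs rows).
    groups
        Cluster (subject) labels, one per row; rows need not be sorted.
    working_correlation
        ``independence``, ``exchangeable`` or ``unstructured``. The
        unstructured option requires ``visit_index`` giving each row's
        position on the shared visit grid.
    visit_index
        Integer occasion index per row (0-based), only for unstructured.
    _layout
        Precomputed ``(starts, sizes)`` for already cluster-sorted input;
        used internally by the variant scan to skip re-sorting.

    Notes
    -----
    With the independence working correlation the estimating equation is
    exactly the normal equations, so ``beta`` equals the OLS solution and
    the fit converges in one step. Non-convergence is reported on the
    returned object (``converged=False``) rather than raised: a scan over
    millions of variants must not abort on one badly-behaved fit.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    X = np.ascontiguousarray(X, dtype=np.float64)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("y must be 1-d and X row-conformable with y")
    n_obs, p = X.shape

    if _layout is not None:
        starts, sizes = _layout
        visit = visit_index
    else:
        order, starts, sizes = _cluster_layout(groups)
        y = y[order]
        X = X[order]
        visit = None if visit_index is None else np.asarray(visit_index)[order]
    n_clusters = len(starts)
    if n_clusters < 2:
        raise ValueError("GEE requires at least two clusters")

    if working_correlation not in ("independence", "exchangeable", "unstructured"):
        raise ValueError(f"unknown working correlation: {working_correlation!r}")
    if working_correlation == "unstructured" and visit is None:
        raise ValueError("unstructured working correlation needs visit_index")

    XtX = X.T @ X
    # rank check once; scans guard monomorphism upstream
    if np.linalg.matrix_rank(XtX) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = np.linalg.solve(XtX, X.T @ y)

    if bias_correction not in (None, "mancl-derouen"):
        raise ValueError(f"unknown bias correction: {bias_correction!r}")

    if working_correlation == "independence":
        e = y - X @ beta
        phi = float(e @ e) / (n_obs - p)
        A_inv = np.linalg.inv(XtX)  # X'R^-1X with R = I
        if bias_correction == "mancl-derouen":
            B_t = _mancl_derouen_B(X, e, starts, sizes, A_inv, "independence", 0.0, None, None)
        else:
            T = np.add.reduceat(X * e[:, None], starts, axis=0)
            B_t = T.T @ T
        robust = A_inv @ B_t @ A_inv
        return GEEFit(
            beta=beta,
            naive_cov=phi * A_inv,
            robust_cov=0.5 * (robust + robust.T),
            corr_params=np.array([]),
            dispersion=phi,
            n_clusters=n_clusters,
            n_obs=n_obs,
            n_iter=1,
            converged=True,
            exog_names=list(exog_names) if exog_names is not None else [],
        )

    pair_count = float(np.sum(sizes * (sizes - 1) / 2.0))
    max_n = int(sizes.max())
    alpha = 0.0
    R = None
    n_visits = int(visit.max()) + 1 if visit is not None else 0
    converged = False
    n_iter = 0
    XtRiX = XtX
    U = None

    for n_iter in range(1, max_iter + 1):
        e = y - X @ beta
        phi = float(e @ e) / (n_obs - p)

        if working_correlation == "exchangeable":
            if pair_count > p:
                esum = np.add.reduceat(e, starts)
                esq = np.add.reduceat(e * e, starts)
                cross = 0.5 * float(np.sum(esum * esum - esq))
                alpha = cross / (phi * (pair_count - p))
                alpha = float(np.clip(alpha, -0.99 / max(max_n - 1, 1), 0.99))
            else:
                alpha = 0.0
            XtRiX, XtRiy, U = _exchangeable_products(X, y, e, starts, sizes, alpha)
        else:  # unstructured
            R = _unstructured_R(e, starts, sizes, visit, n_visits, phi)
            XtRiX = np.zeros((p, p))
            XtRiy = np.zeros(p)
            U = np.zeros((n_clusters, p))
            for ci, (s, n) in enumerate(zip(starts, sizes)):
                v = visit[s : s + n]
                Ri = np.linalg.inv(R[np.ix_(v, v)])
                Xi = X[s : s + n]
                XtRi = Xi.T @ Ri
                XtRiX += XtRi @ Xi
                XtRiy += XtRi @ y[s : s + n]
                U[ci] = XtRi @ e[s : s + n]

        beta_new = np.linalg.solve(XtRiX, XtRiy)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"GEE did not converge in {max_iter} iterations (last step {delta:.2e})",
            stacklevel=2,
        )

    # final residual pass so covariances reflect the returned beta
    e = y - X @ beta
    phi = float(e @ e) / (n_obs - p)
    if working_correlation == "exchangeable":
        XtRiX, _, U = _exchangeable_products(X, y, e, starts, sizes, alpha)
        corr_params = float(alpha)
    else:
        XtRiX = np.zeros((p, p))
        U = np.zeros((n_clusters, p))
        for ci, (s, n) in enumerate(zip(starts, sizes)):
            v = visit[s : s + n]
            Ri = np.linalg.inv(R[np.ix_(v, v)])
            XtRi = X[s : s + n].T @ Ri
            XtRiX += XtRi @ X[s : s + n]
            U[ci] = XtRi @ e[s : s + n]
        corr_params = R

    A_inv = np.linalg.inv(XtRiX)  # (X'R^-1X)^-1; phi cancels in the sandwich
    if bias_correction == "mancl-derouen":
        B_t = _mancl_derouen_B(
            X, e, starts, sizes, A_inv, working_correlation,
            alpha if working_correlation == "exchangeable" else 0.0, R, visit,
        )
    else:
        B_t = U.T @ U
    robust = A_inv @ B_t @ A_inv
    return GEEFit(
        beta=beta,
        naive_cov=phi * A_inv,
        robust_cov=0.5 * (robust + robust.T),
        corr_params=corr_params,
        dispersion=phi,
        n_clusters=n_clusters,
        n_obs=n_obs,
        n_iter=n_iter,
        converged=converged,
        exog_names=list(exog_names) if exog_names is not None else [],
    )


# ---------------------------------------------------------------------------
# Linear mixed model (REML)


def fit_lmm_reml(
    y,
    X,
    groups,
    slope_time=None,
    exog_names=None,
) -> LMMFit:
    """REML linear mixed model with a random intercept and optional random slope.

    ``slope_time`` is the per-row time value (years) carrying the random
    slope; when omitted, or when no cluster has two observations (slope
    variance unidentifiable), an intercept-only random structure is used
    and a warning is emitted in the latter case.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    _, sizes = np.unique(groups, return_counts=True)
    if len(sizes) < 2:
        raise ValueError("mixed model requires at least two clusters")

    random_slope = slope_time is not None
    if random_slope and sizes.max() < 2:
        warnings.warn(
            "all clusters are singletons; random slope dropped (intercept only)",
            stacklevel=2,
        )
        random_slope = False

    if random_slope:
        exog_re = np.column_stack([np.ones(len(y)), np.asarray(slope_time, float)])
    else:
        exog_re = np.ones((len(y), 1))

    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="lbfgs")
        if not res.converged:
            res = model.fit(reml=True, method="powell")

    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    var_int = float(cov_re[0, 0])
    if random_slope:
        var_slope = float(cov_re[1, 1])
        cov_is = float(cov_re[0, 1])
    else:
        var_slope = 0.0
        cov_is = 0.0
    return LMMFit(
        beta=np.asarray(res.fe_params, dtype=float),
        cov_beta=np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]],
        var_intercept=var_int,
        var_slope=var_slope,
        cov_intercept_slope=cov_is,
        var_resid=float(res.scale),
        reml_loglike=float(res.llf),
        converged=bool(res.converged),
        random_slope=random_slope,
        exog_names=list(exog_names) if exog_names is not None else [],
    )
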