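"""Genotype-driven selection (collider) diagnostics.

In a cohort selected on age and genotype, conditioning on inclusion makes
age and the selection-driving genotypes correlated *within the sample*,
even though genotype cannot cause age. A GWAS of baseline age (linear,
robust SEs) and of sex (logistic) among included subjects therefore acts
as a negative-control scan: loci reaching genome-wide significance are
selection artefacts and should be carried as covariates into the
trajectory GWAS, after which re-running the diagnostic adjusted for them
should clear the signal.

The per-variant models are deliberately tiny (trait ~ intercept + dosage,
plus optional adjustment dosages), and both scans are vectorised across
variants so the diagnostic stays cheap at genome scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .scan import GENOME_WIDE_P, genomic_lambda
from .simulate import CohortData

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "SelectionReport",
    "fit_logistic",
    "scan_covariate",
    "selection_report",
    "flag_selection_loci",
]


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    loglike: float
    n_iter: int
    converged: bool
    separation: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald(self):
        z = self.beta / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        if self.separation:
            p = np.full_like(p, np.nan)
        return z, p


@dataclass
class SelectionReport:
    table: pd.DataFrame  # per-variant age and sex association rows
    flagged: list  # variant ids with p < threshold on either trait
    lambda_age: float
    lambda_sex: float
    threshold: float = GENOME_WIDE_P
    adjusted_for: list = field(default_factory=list)


def fit_logistic(X, y, max_iter: int = 50, tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    Uses step-halving when a step fails to improve the log-likelihood.
    Complete separation is detected as coefficients diverging (max |beta|
    beyond 30 on the log-odds scale) and flagged; Wald p-values are then
    reported missing rather than spuriously tiny.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = -n * np.log(2.0)
    converged = False
    separation = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        W = mu * (1 - mu)
        score = X.T @ (y - mu)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step halving on the log-likelihood
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        delta = float(np.max(np.abs(cand - beta)))
        beta, eta, ll = cand, eta_c, ll_c
        if np.max(np.abs(beta)) > 30.0:
            separation = True
            break
        if delta < tol:
            converged = True
            break
    mu = expit(eta)
    W = np.maximum(mu * (1 - mu), 1e-12)
    info = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        separation = True
    return LogisticFit(
        beta=beta, cov=cov, loglike=ll, n_iter=n_iter, converged=converged, separation=separation
    )


def _residualise(M: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Project adjustment columns Z (plus intercept) out of the columns of M."""
    n = M.shape[0]
    ones = np.ones((n, 1))
    Z = ones if Z is None else np.column_stack([ones, Z])
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def _linear_scan(trait: np.ndarray, G: np.ndarray, adjust: np.ndarray | None):
    """Simple-regression age GWAS across variant columns, HC0 robust SEs."""
    Gr = _residualise(G, adjust)
    yr = _residualise(trait[:, None], adjust)[:, 0]
    n = len(yr)
    sxx = np.sum(Gr * Gr, axis=0)
    valid = sxx > 1e-12
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    beta[valid] = (Gr[:, valid].T @ yr) / sxx[valid]
    resid = yr[:, None] - Gr[:, valid] * beta[valid][None, :]
    se[valid] = np.sqrt(np.sum((Gr[:, valid] * resid) ** 2, axis=0)) / sxx[valid]
    # guard against zero residuals
    se = np.where(se > 0, se, np.nan)
    z = beta / se
    return beta, se, 2.0 * stats.norm.sf(np.abs(z)), valid, n


def _batched_info_score(Z, G, W, r):
    """Per-variant Fisher information and score for design [Z, g_j].

    Z is shared (n, q); G holds one dosage column per variant (n, m);
    W, r are (n, m). Returns info (m, p, p) and score (m, p), p = q + 1.
    """
    q = Z.shape[1]
    A = np.einsum("ni,nm,nj->mij", Z, W, Z, optimize=True)  # (m, q, q)
    b = np.einsum("ni,nm,nm->mi", Z, W, G, optimize=True)  # (m, q)
    c = np.sum(W * G * G, axis=0)  # (m,)
    m = G.shape[1]
    info = np.empty((m, q + 1, q + 1))
    info[:, :q, :q] = A
    info[:, :q, q] = b
    info[:, q, :q] = b
    info[:, q, q] = c
    score = np.empty((m, q + 1))
    score[:, :q] = r.T @ Z
    score[:, q] = np.sum(r * G, axis=0)
    return info, score


def _logistic_scan(y: np.ndarray, G: np.ndarray, adjust: np.ndarray | None, max_iter=30):
    """Batched per-variant logistic fits of y on (intercept, adjust, g_j).

    All variants share the Newton iterations, with per-variant parameter
    vectors solved as a batch of small systems. Returns the dosage
    coefficient, its Wald SE and p per variant; diverging fits (complete
    separation) are flagged and reported missing.
    """
    n, m = G.shape
    ones = np.ones((n, 1))
    Z = ones if adjust is None else np.column_stack([ones, adjust])
    q = Z.shape[1]
    B = np.zeros((m, q + 1))
    active = np.ones(m, dtype=bool)
    sep = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Gi = G[:, idx]
        eta = Z @ B[idx, :q].T + Gi * B[idx, q][None, :]  # (n, k)
        mu = expit(eta)
        W = mu * (1 - mu)
        r = y[:, None] - mu
        info, score = _batched_info_score(Z, Gi, W, r)
        # batched solve; singular systems -> separation
        try:
            step = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.full_like(score, np.nan)
            for t in range(len(idx)):
                try:
                    step[t] = np.linalg.solve(info[t], score[t])
                except np.linalg.LinAlgError:
                    pass
        bad = ~np.isfinite(step).all(axis=1)
        B[idx[~bad]] += step[~bad]
        sep[idx[bad]] = True
        active[idx[bad]] = False
        diverged = np.max(np.abs(B[idx]), axis=1) > 30.0
        sep[idx[diverged]] = True
        active[idx[diverged]] = False
        small = np.max(np.abs(step), axis=1) < 1e-8
        active[idx[small & ~bad & ~diverged]] = False
    # Wald SEs at the final estimates
    se = np.full(m, np.nan)
    ok = np.flatnonzero(~sep)
    if ok.size:
        Gi = G[:, ok]
        eta = Z @ B[ok, :q].T + Gi * B[ok, q][None, :]
        mu = expit(eta)
        W = np.maximum(mu * (1 - mu), 1e-12)
        info, _ = _batched_info_score(Z, Gi, W, np.zeros_like(W))
        try:
            cov = np.linalg.inv(info)
            se[ok] = np.sqrt(cov[:, q, q])
        except np.linalg.LinAlgError:
            for t, j in enumerate(ok):
                try:
                    se[j] = np.sqrt(np.linalg.inv(info[t])[q, q])
                except np.linalg.LinAlgError:
                    sep[j] = True
    beta = B[:, q].copy()
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[sep] = np.nan
    beta[sep] = np.nan
    return beta, se, p, sep


def scan_covariate(
    cohort: CohortData,
    trait: str,
    adjust_variant_ids=(),
    variant_ids=None,
) -> pd.DataFrame:
    """GWAS of baseline age (linear) or sex (logistic) across the cohort.

    One row per subject (no repeated measures); monomorphic variants are
    skipped with a log entry. ``adjust_variant_ids`` dosages are included
    as covariates — the mechanism by which flagged selection loci are
    conditioned on when re-checking.
    """
    if trait not in ("age", "sex"):
        raise ValueError("trait must be 'age' or 'sex'")
    meta = cohort.variant_meta
    if variant_ids is None:
        variant_ids = meta["variant_id"].tolist()
    col_of = pd.Series(meta.index.to_numpy(), index=meta["variant_id"])
    cols = col_of.loc[variant_ids].to_numpy()
    adjust = None
    if adjust_variant_ids:
        adjust = np.column_stack([cohort.dosage_of(v) for v in adjust_variant_ids])

    y = (
        cohort.covariates["baseline_age_years"].to_numpy(dtype=float)
        if trait == "age"
        else cohort.covariates["sex"].to_numpy(dtype=float)
    )
    m = len(cols)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    poly = np.zeros(m, dtype=bool)
    chunk = 4000  # bounds the working-set size at genome scale
    for lo in range(0, m, chunk):
        sel = cols[lo : lo + chunk]
        G = cohort.dosages[:, sel].astype(float)
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
        ok = G.std(axis=0) > 0
        poly[lo : lo + chunk] = ok
        if not ok.any():
            continue
        view = slice(lo, lo + len(sel))
        out_idx = np.flatnonzero(ok) + lo
        if trait == "age":
            b, s, pv, _, _ = _linear_scan(y, G[:, ok], adjust)
        else:
            b, s, pv, _ = _logistic_scan(y, G[:, ok], adjust)
        beta[out_idx], se[out_idx], p[out_idx] = b, s, pv
    if (~poly).any():
        logger.info("%d monomorphic variants skipped in %s scan", int((~poly).sum()), trait)
    # a variant conditioned on itself has no residual association by construction
    if adjust_variant_ids:
        own = pd.Index(variant_ids).isin(adjust_variant_ids)
        beta[own], se[own], p[own] = 0.0, np.nan, 1.0
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": meta["chrom"].to_numpy()[cols],
            "pos": meta["pos"].to_numpy()[cols],
            f"beta_{trait}": beta,
            f"se_{trait}": se,
            f"p_{trait}": p,
            "tested": poly,
        }
    )


def selection_report(
    cohort: CohortData,
    threshold: float = GENOME_WIDE_P,
    adjust_variant_ids=(),
    variant_ids=None,
    traits=("age", "sex"),
) -> SelectionReport:
    """Run the negative-control GWAS and flag selection-associated loci.

    ``traits`` restricts which scans run (the sex scan is the expensive
    one at genome scale); flags pool significant hits across the traits
    that were run.
    """
    tables = {
        t: scan_covariate(cohort, t, adjust_variant_ids, variant_ids) for t in traits
    }
    names = list(tables)
    table = tables[names[0]]
    for t in names[1:]:
        table = table.merge(
            tables[t][["variant_id", f"beta_{t}", f"se_{t}", f"p_{t}"]], on="variant_id"
        )
    sig = np.zeros(len(table), dtype=bool)
    for t in names:
        sig |= (table[f"p_{t}"] < threshold).to_numpy()
    flagged = table.loc[sig, "variant_id"].tolist()

    def lam(t):
        if t not in tables:
            return np.nan
        return genomic_lambda(p=table[f"p_{t}"].dropna().to_numpy())

    return SelectionReport(
        table=table,
        flagged=flagged,
        lambda_age=lam("age"),
        lambda_sex=lam("sex"),
        threshold=threshold,
        adjusted_for=list(adjust_variant_ids),
    )


def flag_selection_loci(report: SelectionReport, covariates: list | None = None) -> list:
    """Append flagged loci to a scan covariate list (deduplicated, ordered)."""
    out = list(covariates) if covariates else []
    for vid in report.flagged:
        if vid not in out:
            out.append(vid)
    return out
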