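"""Synthetic trial cohorts with the structure the trajectory GWAS assumes.

The generator emulates a prevention-trial cohort of cognitively normal
older adults: candidates aged 65-83 at baseline (mean 73.4, SD 5.3),
screened into the study by a logistic rule in baseline age and the dosages
of two designated risk loci (biallelic stand-ins for the APOE/TOMM40 risk
haplotypes that drove trial eligibility), then followed with cognitive
testing every 6 months for up to 5 years (1 to 11 occasions; monotone
dropout). Each subject's latent cognition follows a two-slope linear
spline with a knot at one year; per-variant genetic effects may act on any
of the four trajectory parameters (intercept, baseline-age gradient,
slope 1, slope 2), in phenotype-SD units per allele with slopes per year.

Genotypes are drawn from Hardy-Weinberg proportions at frequencies sampled
within a configurable range; optional LD blocks copy a block anchor with a
small per-subject refresh probability so clumping logic can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "TrueEffects",
    "CohortData",
    "simulate_genotypes",
    "simulate_covariates",
    "candidate_cohort",
    "apply_selection",
    "simulate_trajectories",
    "simulate_cohort",
]

_BASES = ("A", "C", "G", "T")
_DOMAINS = ("attention", "executive", "memory", "learning", "language")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults encode the trial design being emulated: baseline ages 65-83
    (mean 73.4, SD 5.3), visits every 182.5 days to day 1825 (11 scheduled
    occasions), a knot at day 365, and a per-visit retention such that the
    mean number of occasions is close to 5.9 — the average implied by a
    3,465-subject trial contributing 20,440 assessment rows. Trajectory and
    noise scales are in z-units; slopes per year.
    """

    n_candidates: int = 3465
    n_variants: int = 5000
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    age_range_years: tuple[float, float] = (65.0, 83.0)
    age_mean: float = 73.4
    age_sd: float = 5.3
    visit_spacing_days: float = 182.5
    max_followup_days: float = 1825.0
    knot_days: float = 365.0
    dropout_prob_per_visit: float = 0.13
    # mean trajectory (z units; slopes per year; age gradient per year of age)
    mean_intercept: float = 0.0
    mean_age_slope: float = -0.03
    mean_slope1: float = 0.15
    mean_slope2: float = 0.02
    # noise
    resid_sd: float = 0.5
    random_intercept_sd: float = 0.8
    random_slope_sd: float = 0.07
    test_noise_sd: float = 0.3
    within_corr_structure: str = "independence"  # independence | exchangeable | ar1
    within_corr: float = 0.3
    n_tests_per_domain: int = 2
    # LD structure: block size 1 means independent variants
    ld_block_size: int = 1
    ld_flip_prob: float = 0.02
    imputation_r2_range: tuple[float, float] = (0.55, 1.0)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie strictly inside (0, 1)")
        if self.n_candidates < 1 or self.n_variants < 1:
            raise ValueError("n_candidates and n_variants must be >= 1")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be positive")
        if not (0.0 <= self.dropout_prob_per_visit < 1.0):
            raise ValueError("dropout_prob_per_visit must be in [0, 1)")
        if self.within_corr_structure not in ("independence", "exchangeable", "ar1"):
            raise ValueError("unknown within_corr_structure")

    @property
    def visit_grid(self) -> np.ndarray:
        return np.arange(0.0, self.max_followup_days + 1e-9, self.visit_spacing_days)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueEffects:
    """Ground-truth genetic effects and selection coefficients.

    ``gammas`` maps a variant id to its effect quadruple
    (intercept, age gradient, slope 1, slope 2); variants not listed have
    no effect. Selection into the study follows
    ``logit P = intercept + age_coeff*(age - age_mean) + risk_coeff*(d1 + d2)``
    over the two risk-locus dosages; zero coefficients give unbiased
    sampling, an empty ``gammas`` the global null.
    """

    gammas: dict[str, np.ndarray] = field(default_factory=dict)
    risk_variant_ids: tuple[str, str] = ("var0001", "var0002")
    selection_age_coeff: float = 0.0
    selection_risk_coeff: float = 0.0
    selection_intercept: float = 0.0

    @classmethod
    def null(cls, risk_variant_ids=("var0001", "var0002")) -> "TrueEffects":
        return cls(risk_variant_ids=tuple(risk_variant_ids))

    @classmethod
    def trial_selection(
        cls,
        risk_variant_ids=("var0001", "var0002"),
        age_coeff: float = 0.4,
        risk_coeff: float = 2.0,
        intercept: float = -3.0,
    ) -> "TrueEffects":
        """Age- and risk-genotype-driven enrolment, as in a risk-stratified trial.

        Defaults approximate a near-threshold eligibility rule (steep
        logistic in age and risk dosage), the regime in which selection
        induces a clearly detectable genotype-age association in the
        enrolled sample.
        """
        return cls(
            risk_variant_ids=tuple(risk_variant_ids),
            selection_age_coeff=age_coeff,
            selection_risk_coeff=risk_coeff,
            selection_intercept=intercept,
        )

    def with_effect(self, variant_id: str, quad) -> "TrueEffects":
        gammas = dict(self.gammas)
        gammas[variant_id] = np.asarray(quad, dtype=float)
        return replace(self, gammas=gammas)


@dataclass
class CohortData:
    """Genotypes, covariates and long-format phenotypes for one cohort."""

    dosages: np.ndarray  # subjects x variants, values in [0, 2]
    subject_ids: np.ndarray
    variant_meta: pd.DataFrame  # variant_id, chrom, pos, ref, alt, imputation_r2
    covariates: pd.DataFrame  # indexed 0..n-1, has subject_id column
    phenotypes: pd.DataFrame  # subject_id, time_days, test_id, score

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant_id: str) -> int:
        idx = self.variant_meta.index[self.variant_meta["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant: {variant_id}")
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_subjects(self, mask: np.ndarray) -> "CohortData":
        ids = set(self.subject_ids[mask])
        phen = self.phenotypes
        if len(phen):
            phen = phen.loc[phen["subject_id"].isin(ids)].reset_index(drop=True)
        return CohortData(
            dosages=self.dosages[mask],
            subject_ids=self.subject_ids[mask],
            variant_meta=self.variant_meta.copy(),
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            phenotypes=phen,
        )

    def validate(self) -> None:
        if self.dosages.shape != (self.n_subjects, len(self.variant_meta)):
            raise ValueError("dosage matrix shape disagrees with metadata")
        d = self.dosages[~np.isnan(self.dosages)]
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if len(self.phenotypes):
            keys = self.phenotypes[["subject_id", "time_days", "test_id"]]
            if keys.duplicated().any():
                raise ValueError("duplicated (subject, time, test) phenotype rows")
            has_base = self.phenotypes.groupby("subject_id")["time_days"].min()
            if (has_base != 0).any():
                raise ValueError("every phenotyped subject needs a time_days == 0 row")


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig, rng=None):
    """Draw a HWE dosage matrix plus variant metadata.

    Variants are laid out along chromosomes 1..22 with increasing
    positions. When ``ld_block_size > 1`` consecutive variants within a
    block copy the block anchor's genotypes, each subject re-drawn from
    HWE with probability ``ld_flip_prob``, giving high pairwise r2 inside
    blocks and independence across them.
    """
    rng = config.rng() if rng is None else rng
    n, m = config.n_candidates, config.n_variants
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)

    block = max(int(config.ld_block_size), 1)
    geno = np.empty((n, m), dtype=np.float64)
    for j in range(m):
        if block > 1 and j % block != 0:
            anchor = geno[:, (j // block) * block]
            fresh = rng.binomial(2, freqs[(j // block) * block], size=n)
            flip = rng.random(n) < config.ld_flip_prob
            geno[:, j] = np.where(flip, fresh, anchor)
            freqs[j] = freqs[(j // block) * block]
        else:
            geno[:, j] = rng.binomial(2, freqs[j], size=n)

    n_blocks_total = (m + block - 1) // block
    block_ids = np.arange(m) // block
    chroms = (block_ids * 22 // max(n_blocks_total, 1)) % 22 + 1
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, 23):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = 10_000 + np.arange(len(idx)) * 5_000

    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    r2lo, r2hi = config.imputation_r2_range
    meta = pd.DataFrame(
        {
            "variant_id": [f"var{j + 1:04d}" for j in range(m)],
            "chrom": chroms.astype(str),
            "pos": pos,
            "ref": [_BASES[i] for i in ref_i],
            "alt": [_BASES[i] for i in alt_i],
            "imputation_r2": rng.uniform(r2lo, r2hi, size=m),
            "true_freq": freqs,
        }
    )
    return geno, meta


def simulate_covariates(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Baseline covariates: age (truncated normal), sex and lifestyle."""
    rng = config.rng() if rng is None else rng
    n = config.n_candidates
    lo, hi = config.age_range_years
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in range(n)],
            "baseline_age_years": age,
            "sex": rng.integers(0, 2, size=n),
            "education_years": np.clip(rng.normal(14.0, 3.0, size=n), 6, 22).round(1),
            "alcohol": np.round(rng.gamma(2.0, 3.0, size=n), 1),
            "smoking": rng.binomial(1, 0.4, size=n),
            "bmi": np.clip(rng.normal(27.0, 4.5, size=n), 16, 50).round(1),
        }
    )


def candidate_cohort(config: SimulationConfig, rng=None) -> CohortData:
    """Genotypes + covariates for the screened candidate pool (no phenotypes)."""
    rng = config.rng() if rng is None else rng
    geno, meta = simulate_genotypes(config, rng)
    covar = simulate_covariates(config, rng)
    covar["subject_id"] = covar["subject_id"].astype(str)
    return CohortData(
        dosages=geno,
        subject_ids=covar["subject_id"].to_numpy(),
        variant_meta=meta,
        covariates=covar,
        phenotypes=pd.DataFrame(columns=["subject_id", "time_days", "test_id", "score"]),
    )


# ---------------------------------------------------------------------------
# selection


def apply_selection(candidates: CohortData, effects: TrueEffects, config: SimulationConfig, rng=None):
    """Screen candidates into the study through the logistic selection rule.

    Returns the included sub-cohort plus an inclusion log (one row per
    candidate: inclusion probability, draw, risk-dosage sum). The risk
    stratum is assigned from the risk-locus dosages of included subjects
    (``high`` when the summed risk dosage is >= 1).
    """
    rng = config.rng() if rng is None else rng
    risk = np.zeros(candidates.n_subjects)
    for vid in effects.risk_variant_ids:
        risk = risk + candidates.dosage_of(vid)
    age_c = candidates.covariates["baseline_age_years"].to_numpy() - config.age_mean
    logit = (
        effects.selection_intercept
        + effects.selection_age_coeff * age_c
        + effects.selection_risk_coeff * risk
    )
    p_inc = expit(logit)
    if effects.selection_age_coeff == 0 and effects.selection_risk_coeff == 0 and effects.selection_intercept == 0:
        # unbiased sampling shortcut: include everyone (expit(0) applied uniformly
        # keeps frequencies unbiased either way; keeping all is the useful default)
        included = np.ones(candidates.n_subjects, dtype=bool)
    else:
        included = rng.random(candidates.n_subjects) < p_inc
    if not included.any():
        raise ValueError("selection excluded every candidate; relax the coefficients")
    log = pd.DataFrame(
        {
            "subject_id": candidates.subject_ids,
            "p_include": p_inc,
            "included": included,
            "risk_dosage_sum": risk,
        }
    )
    cohort = candidates.subset_subjects(included)
    cohort.covariates = cohort.covariates.copy()
    cohort.covariates["risk_stratum"] = np.where(
        log.loc[log["included"], "risk_dosage_sum"].to_numpy() >= 1.0, "high", "low"
    )
    return cohort, log


# ---------------------------------------------------------------------------
# trajectories


def _test_ids(config: SimulationConfig) -> list[str]:
    return [f"{d}_{i + 1}" for d in _DOMAINS for i in range(config.n_tests_per_domain)]


def _visit_residuals(rng, n_subj, n_vis, config: SimulationConfig) -> np.ndarray:
    """Visit-level residuals with the configured within-subject correlation."""
    sd, rho = config.resid_sd, config.within_corr
    if config.within_corr_structure == "independence" or rho == 0:
        return rng.normal(0.0, sd, size=(n_subj, n_vis))
    if config.within_corr_structure == "exchangeable":
        shared = rng.normal(0.0, 1.0, size=(n_subj, 1))
        own = rng.normal(0.0, 1.0, size=(n_subj, n_vis))
        return sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)
    # ar1
    e = np.empty((n_subj, n_vis))
    e[:, 0] = rng.normal(0.0, 1.0, size=n_subj)
    innov_sd = np.sqrt(1 - rho**2)
    for v in range(1, n_vis):
        e[:, v] = rho * e[:, v - 1] + rng.normal(0.0, innov_sd, size=n_subj)
    return sd * e


def simulate_trajectories(
    included: CohortData, effects: TrueEffects, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Generate long-format raw test scores along the two-slope mean curve.

    The latent trajectory at time t (days) is

        mu = b0 + b_age*(age - age_mean) + b_s1*s1(t) + b_s2*s2(t)
             + sum_v dosage_v * (gamma_v . [1, age_c, s1, s2])
             + subject random intercept + random slope * t/365 + residual

    with s1/s2 in years. Each raw test score is an affine rescaling of the
    latent value plus test-specific noise, so that baseline
    z-standardisation is a non-trivial operation. Dropout is monotone:
    once a subject misses a visit, all later visits are missing; the
    baseline visit is always observed (1 to 11 occasions at defaults).
    """
    rng = config.rng() if rng is None else rng
    n = included.n_subjects
    grid = config.visit_grid
    n_vis = len(grid)

    age_c = included.covariates["baseline_age_years"].to_numpy() - config.age_mean
    s1 = np.minimum(grid, config.knot_days) / 365.0
    s2 = np.maximum(grid - config.knot_days, 0.0) / 365.0
    years = grid / 365.0

    mu = (
        config.mean_intercept
        + config.mean_age_slope * age_c[:, None]
        + config.mean_slope1 * s1[None, :]
        + config.mean_slope2 * s2[None, :]
    )
    for vid, quad in effects.gammas.items():
        g = included.dosage_of(vid)[:, None]
        quad = np.asarray(quad, dtype=float)
        mu = mu + g * (
            quad[0] + quad[1] * age_c[:, None] + quad[2] * s1[None, :] + quad[3] * s2[None, :]
        )

    b0 = rng.normal(0.0, config.random_intercept_sd, size=n) if config.random_intercept_sd > 0 else np.zeros(n)
    b1 = rng.normal(0.0, config.random_slope_sd, size=n) if config.random_slope_sd > 0 else np.zeros(n)
    latent = mu + b0[:, None] + b1[:, None] * years[None, :]
    latent = latent + _visit_residuals(rng, n, n_vis, config)

    # monotone dropout: subject observed at visits 0..k-1
    if config.dropout_prob_per_visit > 0:
        drop = rng.random((n, n_vis - 1)) < config.dropout_prob_per_visit if n_vis > 1 else np.zeros((n, 0), bool)
        alive = np.concatenate([np.ones((n, 1), bool), np.cumprod(~drop, axis=1).astype(bool)], axis=1)
    else:
        alive = np.ones((n, n_vis), dtype=bool)

    tests = _test_ids(config)
    locs = rng.uniform(10.0, 90.0, size=len(tests))
    scales = rng.uniform(5.0, 15.0, size=len(tests))

    subj_idx, vis_idx = np.nonzero(alive)
    lat_obs = latent[subj_idx, vis_idx]
    n_rows = len(lat_obs)
    frames = []
    for k, test in enumerate(tests):
        noise = (
            rng.normal(0.0, config.test_noise_sd, size=n_rows)
            if config.test_noise_sd > 0
            else np.zeros(n_rows)
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": included.subject_ids[subj_idx],
                    "time_days": grid[vis_idx],
                    "test_id": test,
                    "score": locs[k] + scales[k] * (lat_obs + noise),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: SimulationConfig, effects: TrueEffects | None = None, rng=None):
    """End-to-end draw: candidates -> selection -> trajectories.

    Returns ``(cohort, inclusion_log)`` where ``cohort`` is the included
    sub-cohort carrying its phenotype rows.
    """
    rng = config.rng() if rng is None else rng
    effects = TrueEffects.null() if effects is None else effects
    candidates = candidate_cohort(config, rng)
    cohort, log = apply_selection(candidates, effects, config, rng)
    cohort.phenotypes = simulate_trajectories(cohort, effects, config, rng)
    return cohort, log
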