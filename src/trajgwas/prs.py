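"""Polygenic risk scores and their trajectory associations.

A score is built from an external GWAS weights table: only genome-wide
significant variants (source p < 5e-8) are used, strand-ambiguous (A/T,
C/G) variants are dropped, weights are aligned to the cohort's alt allele
(negated when the external effect allele is the cohort ref), and the
retained set is LD-clumped against the cohort's own genotypes so each
signal contributes once. The per-subject score is the weighted dosage
sum, standardised in-sample so association betas read per SD of score.

Trajectory association reuses the four-parameter spline model: score main
effect (baseline level), score x age, score x slope 1 and score x slope 2,
fitted by REML mixed model (random intercept + slope) with a GEE
fallback, adjusting for the same covariates as the variant scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import fit_gee, fit_lmm_reml
from .scan import GENOME_WIDE_P, PARAM_BLOCKS, build_scan_design, clump
from .simulate import CohortData

__all__ = [
    "PRSModel",
    "PRSAssociation",
    "select_and_align",
    "compute_prs",
    "test_prs_trajectory",
    "bonferroni_threshold",
]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class PRSModel:
    trait: str
    variants: pd.DataFrame  # variant_id, effect_allele, weight, source_p, aligned_weight
    ledger: pd.DataFrame  # variant_id, reason for every dropped weight row

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class PRSAssociation:
    trait: str
    outcome: str
    blocks: dict  # block -> {"beta": ..., "se": ..., "p": ...}
    family: str  # "lmm" or "gee"
    converged: bool
    n_subjects: int = 0

    def as_row(self) -> dict:
        row = {"trait": self.trait, "outcome": self.outcome, "family": self.family}
        for b, v in self.blocks.items():
            row.update({f"{b}_beta": v["beta"], f"{b}_se": v["se"], f"{b}_p": v["p"]})
        return row


def select_and_align(
    weights: pd.DataFrame,
    cohort: CohortData,
    trait: str = "trait",
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
) -> PRSModel:
    """Filter, clump and allele-align an external weights table.

    ``weights`` needs columns variant_id, effect_allele, other_allele,
    beta, p. Pipeline: p-filter -> drop strand-ambiguous -> match to
    cohort variants -> align sign to the cohort alt allele -> LD-clump by
    source p against cohort dosages. Every dropped row lands in the
    ledger with its reason; zero surviving variants is an error.
    """
    meta = cohort.variant_meta.set_index("variant_id")
    ledger_rows = []
    kept = []
    for row in weights.itertuples(index=False):
        if not (row.p < p_threshold):
            ledger_rows.append({"variant_id": row.variant_id, "reason": "source_p"})
            continue
        pair = frozenset((str(row.effect_allele), str(row.other_allele)))
        if pair in _AMBIGUOUS:
            ledger_rows.append({"variant_id": row.variant_id, "reason": "ambiguous"})
            continue
        if row.variant_id not in meta.index:
            ledger_rows.append({"variant_id": row.variant_id, "reason": "unmatched"})
            continue
        m = meta.loc[row.variant_id]
        if row.effect_allele == m["alt"] and row.other_allele == m["ref"]:
            sign = 1.0
        elif row.effect_allele == m["ref"] and row.other_allele == m["alt"]:
            sign = -1.0
        else:
            ledger_rows.append({"variant_id": row.variant_id, "reason": "allele_mismatch"})
            continue
        kept.append(
            {
                "variant_id": row.variant_id,
                "chrom": m["chrom"],
                "pos": int(m["pos"]),
                "effect_allele": row.effect_allele,
                "weight": float(row.beta),
                "source_p": float(row.p),
                "aligned_weight": sign * float(row.beta),
            }
        )
    kept = pd.DataFrame(kept)
    if not len(kept):
        raise ValueError("no variants survive PRS selection/alignment")

    # clump by source p against cohort LD; reuse the scan's greedy rule
    clump_in = kept.rename(columns={"source_p": "clump_p"})
    index_ids, assignments = clump(
        clump_in,
        "clump",
        cohort.dosages,
        cohort.variant_meta,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
    )
    dropped = set(kept["variant_id"]) - set(index_ids)
    for vid in kept["variant_id"]:
        if vid in dropped:
            ledger_rows.append({"variant_id": vid, "reason": "clumped"})
    kept = kept.loc[kept["variant_id"].isin(index_ids)].reset_index(drop=True)
    return PRSModel(
        trait=trait,
        variants=kept,
        ledger=pd.DataFrame(ledger_rows, columns=["variant_id", "reason"]),
    )


def compute_prs(model: PRSModel, cohort: CohortData, standardize: bool = True) -> np.ndarray:
    """Weighted dosage sum per subject, standardised in-sample.

    Missing dosages are mean-imputed per variant. Raises when the raw
    scores are constant (zero SD cannot be standardised).
    """
    cols = [cohort.variant_index(v) for v in model.variants["variant_id"]]
    D = cohort.dosages[:, cols].astype(float)
    col_mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), col_mean[None, :], D)
    raw = D @ model.variants["aligned_weight"].to_numpy()
    if not standardize:
        return raw
    sd = raw.std(ddof=1)
    if not sd > 0:
        raise ValueError("PRS is constant across subjects; cannot standardise")
    return (raw - raw.mean()) / sd


def test_prs_trajectory(
    cohort: CohortData,
    outcome: pd.DataFrame,
    score: np.ndarray,
    trait: str = "trait",
    outcome_name: str = "global",
    pcs: np.ndarray | None = None,
    risk_variant_ids=(),
    knot_days: float = 365.0,
    age_ref: float | None = None,
    family: str = "lmm",
) -> PRSAssociation:
    """Association of a standardised score with the four trajectory parameters.

    ``family='lmm'`` fits a REML mixed model (random intercept + random
    slope on total time); on non-convergence — or on request — an
    exchangeable GEE with robust SEs is used instead.
    """
    design = build_scan_design(
        cohort,
        outcome,
        pcs=pcs,
        risk_variant_ids=risk_variant_ids,
        knot_days=knot_days,
        age_ref=age_ref,
    )
    s = np.asarray(score, dtype=float)[design.subj_of_row]
    X = np.column_stack([design.X_base, s, s * design.age_c, s * design.s1, s * design.s2])
    names = design.base_names + ["prs", "prs_x_age", "prs_x_s1", "prs_x_s2"]
    p_base = len(design.base_names)

    used = family
    if family == "lmm":
        total_years = design.s1 + design.s2
        fit = fit_lmm_reml(design.y, X, design.groups, slope_time=total_years, exog_names=names)
        if not fit.converged:
            used = "gee"
    if used == "gee" or family == "gee":
        fit = fit_gee(
            design.y,
            X,
            design.groups,
            working_correlation="exchangeable",
            exog_names=names,
            _layout=(design.starts, design.sizes),
        )
        used = "gee"
    _, p = fit.wald()
    se = fit.robust_se if used == "gee" else fit.se
    blocks = {
        block: {
            "beta": float(fit.beta[p_base + k]),
            "se": float(se[p_base + k]),
            "p": float(p[p_base + k]),
        }
        for k, block in enumerate(PARAM_BLOCKS)
    }
    return PRSAssociation(
        trait=trait,
        outcome=outcome_name,
        blocks=blocks,
        family=used,
        converged=bool(fit.converged),
        n_subjects=int(len(np.unique(design.groups))),
    )


def bonferroni_threshold(n_models: int, alpha: float = 0.05, rounded: bool = True) -> float:
    """Family-wise significance threshold alpha / n.

    With ``rounded`` (the default) the threshold is presentation-rounded
    to one significant figure, e.g. 6 models -> 0.008, 72 models -> 7e-4.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    raw = alpha / n_models
    if not rounded:
        return raw
    exponent = math.floor(math.log10(raw))
    return round(raw, -exponent)
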