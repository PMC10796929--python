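"""Variant-level quality control and ancestry principal components.

Filters follow the usual array-GWAS conventions: site call rate >= 95%,
Hardy-Weinberg exact-test p >= 1e-8, MAF >= 1%, imputation r2 >= 0.7 and
expected minor allele count EMAC = 2*N*MAF*r2 > 200 (at N = 2515 and
r2 = 1 that bound corresponds to a MAF just above 4%). The HWE test is
the exact conditional test on heterozygote counts given the allele
totals, evaluated with a log-space recursion so p-values stay accurate
down to the filtering threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "hwe_exact_test",
    "compute_maf",
    "emac",
    "variant_qc_table",
    "filter_variants",
    "genotype_pca",
    "QCThresholds",
]


@dataclass
class QCThresholds:
    call_rate: float = 0.95
    hwe_p: float = 1e-8
    maf: float = 0.01
    imputation_r2: float = 0.7
    emac: float = 200.0


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one. The
    heterozygote-count distribution is built by the standard ratio
    recursion in log space:

        P(h+2) / P(h) = (nA - h) * (nB - h) / ((h + 2) * (h + 1) ... )

    working down/up from the observed value, which is numerically stable
    for realistic sample sizes.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")

    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    n_rare = min(n_alt, n_ref)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    het_values, probs = hwe_het_distribution(n, n_rare)
    p_obs = probs[np.searchsorted(het_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_het_distribution(n: int, n_rare: int):
    """Exact conditional distribution of the heterozygote count.

    Given ``n`` genotyped individuals and ``n_rare`` copies of the rarer
    allele, returns the attainable het counts (which share the parity of
    ``n_rare``) and their probabilities, built by the log-space ratio
    recursion. This is the distribution the exact test sums over.
    """
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    log_p = np.zeros(len(het_values))
    for i in range(1, len(het_values)):
        h = het_values[i - 1]
        # rare/common homozygote counts at het = h
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # ratio P(h+2)/P(h) = 4 * rare_hom * common_hom / ((h+1)(h+2))
        log_p[i] = log_p[i - 1] + (
            np.log(4.0 * rare_hom * common_hom) - np.log((h + 1.0) * (h + 2.0))
        )
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()
    return het_values, probs


def compute_maf(dosage: np.ndarray):
    """Alt-allele frequency and minor allele frequency from a dosage column.

    Missing (NaN) entries are excluded from the denominator.
    """
    d = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("all dosages missing for variant")
    alt_freq = float(d[ok].mean() / 2.0)
    return alt_freq, min(alt_freq, 1.0 - alt_freq)


def emac(n_subjects: int, maf: float, imputation_r2: float) -> float:
    """Expected minor allele count: 2 * N * MAF * imputation r2."""
    return 2.0 * n_subjects * maf * imputation_r2


def variant_qc_table(
    dosages: np.ndarray,
    variant_meta: pd.DataFrame,
    call_rate: np.ndarray | None = None,
    hwe_from_dosages: bool = True,
) -> pd.DataFrame:
    """Assemble the per-variant QC metrics the filter consumes.

    ``hwe_from_dosages`` rounds dosages to hard genotypes for the exact
    test; set False for imputed data where HWE on rounded dosages is not
    meaningful (hwe_p is then reported as 1).
    """
    n, m = dosages.shape
    mafs = np.empty(m)
    alt_freqs = np.empty(m)
    hwe = np.ones(m)
    for j in range(m):
        alt_freqs[j], mafs[j] = compute_maf(dosages[:, j])
        if hwe_from_dosages:
            d = dosages[:, j]
            d = d[~np.isnan(d)]
            g = np.rint(d).astype(int)
            hwe[j] = hwe_exact_test(
                int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
            )
    out = variant_meta[["variant_id", "chrom", "pos", "ref", "alt", "imputation_r2"]].copy()
    out["call_rate"] = 1.0 if call_rate is None else np.asarray(call_rate, float)
    out["alt_freq"] = alt_freqs
    out["maf"] = mafs
    out["hwe_p"] = hwe
    out["emac"] = emac(n, out["maf"].to_numpy(), out["imputation_r2"].to_numpy())
    return out


#: fixed order in which the exclusion reasons are checked
_RULES = ("call_rate", "hwe", "maf", "imputation_r2", "emac")


def filter_variants(qc_table: pd.DataFrame, thresholds: QCThresholds | None = None):
    """Apply the QC filters; return (kept_ids, exclusion ledger).

    A variant is kept iff it passes every rule; the ledger records the
    first failing rule per excluded variant (each excluded variant appears
    exactly once).
    """
    th = thresholds or QCThresholds()
    fails = {
        "call_rate": qc_table["call_rate"] < th.call_rate,
        "hwe": qc_table["hwe_p"] < th.hwe_p,
        "maf": qc_table["maf"] < th.maf,
        "imputation_r2": qc_table["imputation_r2"] < th.imputation_r2,
        "emac": qc_table["emac"] <= th.emac,
    }
    reason = pd.Series(pd.NA, index=qc_table.index, dtype="object")
    for rule in _RULES:
        reason = reason.mask(reason.isna() & fails[rule], rule)
    excluded = reason.notna()
    ledger = pd.DataFrame(
        {
            "variant_id": qc_table.loc[excluded, "variant_id"].to_numpy(),
            "reason": reason[excluded].to_numpy(),
        }
    )
    kept = qc_table.loc[~excluded, "variant_id"].tolist()
    return kept, ledger


def genotype_pca(dosages: np.ndarray, k: int = 5, thin_step: int = 1):
    """Ancestry principal components from standardised dosages.

    Each variant column is centred and scaled as (d - 2p)/sqrt(2p(1-p));
    monomorphic variants are dropped. Scores are the left singular vectors
    scaled by their singular values (the usual PC scores); also returns the
    fraction of standardised variance each PC explains. ``thin_step``
    subsamples every k-th variant, a cheap stand-in for LD pruning.
    """
    D = np.asarray(dosages, dtype=float)[:, ::max(int(thin_step), 1)]
    n, m = D.shape
    if n < k + 1:
        raise ValueError("need at least k+1 subjects for k components")
    # mean-impute missing before standardising
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D = np.where(nan_mask, col_mean[None, :], D)
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    D = D[:, poly]
    p = p[poly]
    Z = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(k, len(s))
    scores = U[:, :k] * s[:k]
    explained = (s[:k] ** 2) / (s**2).sum()
    return scores, explained
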