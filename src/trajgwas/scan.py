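"""Per-variant trajectory GWAS: four-parameter GEE scan, inflation, clumping.

Each variant enters one Gaussian GEE as an additive dosage with
interactions against the trajectory design — a main effect (baseline
level), an interaction with centred baseline age, and interactions with
the two spline slopes — on top of a covariate set of age, sex, the two
risk-locus dosages and the top ancestry principal components. Robust
(sandwich) Wald tests give one p-value per genetic parameter. Lifestyle
covariates (education, alcohol, smoking, BMI) are deliberately *not*
adjusted: they are plausibly downstream of genotype, and conditioning on
them can open collider paths in a risk-selected cohort. A flag exists for
users who insist.

The shared parts of the design (covariate columns, cluster layout) are
built once; each variant's fit reuses them, which keeps a scan over
thousands of variants to a few milliseconds per model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import fit_gee
from .phenotypes import build_trajectory_basis
from .simulate import CohortData

logger = logging.getLogger(__name__)

__all__ = [
    "ScanDesign",
    "ScanSummary",
    "build_scan_design",
    "scan_variant",
    "run_scan",
    "genomic_lambda",
    "clump",
    "lookup_variants",
    "qq_table",
    "manhattan_table",
    "GENOME_WIDE_P",
]

GENOME_WIDE_P = 5e-8
PARAM_BLOCKS = ("intercept", "age", "slope1", "slope2")
_CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class ScanDesign:
    """Precomputed covariate design shared by every variant's model."""

    y: np.ndarray  # outcome, cluster-sorted
    X_base: np.ndarray  # covariate columns, cluster-sorted
    base_names: list[str]
    starts: np.ndarray  # reduceat cluster boundaries
    sizes: np.ndarray
    subj_of_row: np.ndarray  # cohort subject index per (sorted) row
    age_c: np.ndarray  # per-row centred age (years)
    s1: np.ndarray  # per-row spline columns (years)
    s2: np.ndarray
    groups: np.ndarray


@dataclass
class ScanSummary:
    lambdas: dict
    n_tested: int
    n_converged: int
    n_significant: int
    n_skipped: int
    threshold: float = GENOME_WIDE_P
    skipped: list = field(default_factory=list)


def build_scan_design(
    cohort: CohortData,
    outcome: pd.DataFrame,
    pcs: np.ndarray | None = None,
    risk_variant_ids=(),
    knot_days: float = 365.0,
    age_ref: float | None = None,
    adjust_lifestyle: bool = False,
) -> ScanDesign:
    """Merge outcome rows with covariates and freeze the scan design.

    ``outcome`` is a long table (subject_id, time_days, z). ``pcs`` is a
    subjects-by-k matrix aligned with ``cohort.subject_ids``.
    """
    covar = cohort.covariates.set_index("subject_id")
    rows = outcome[["subject_id", "time_days", "z"]].copy()
    rows = rows.sort_values(["subject_id", "time_days"], kind="stable").reset_index(drop=True)

    subj_pos = pd.Series(
        np.arange(cohort.n_subjects), index=pd.Index(cohort.subject_ids)
    )
    subj_of_row = subj_pos.loc[rows["subject_id"]].to_numpy()
    age = covar["baseline_age_years"].loc[rows["subject_id"]].to_numpy(dtype=float)
    if age_ref is None:
        age_ref = float(covar["baseline_age_years"].mean())

    basis = build_trajectory_basis(
        rows["time_days"].to_numpy(), age, knot_days=knot_days, age_ref=age_ref
    )
    cols = [basis["intercept"], basis["age_c"], basis["s1"], basis["s2"]]
    names = ["intercept", "age_c", "s1", "s2"]

    cols.append(covar["sex"].loc[rows["subject_id"]].to_numpy(dtype=float))
    names.append("sex")
    for vid in risk_variant_ids:
        cols.append(cohort.dosage_of(vid)[subj_of_row])
        names.append(f"risk_{vid}")
    if adjust_lifestyle:
        for c in ("education_years", "alcohol", "smoking", "bmi"):
            cols.append(covar[c].loc[rows["subject_id"]].to_numpy(dtype=float))
            names.append(c)
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        for k in range(pcs.shape[1]):
            cols.append(pcs[subj_of_row, k])
            names.append(f"PC{k + 1}")

    X = np.column_stack(cols)
    groups = pd.factorize(rows["subject_id"], sort=False)[0]
    starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    sizes = np.diff(np.r_[starts, len(groups)])
    return ScanDesign(
        y=rows["z"].to_numpy(dtype=float),
        X_base=X,
        base_names=names,
        starts=starts,
        sizes=sizes,
        subj_of_row=subj_of_row,
        age_c=basis["age_c"].to_numpy(),
        s1=basis["s1"].to_numpy(),
        s2=basis["s2"].to_numpy(),
        groups=groups,
    )


def _variant_fit(design: ScanDesign, dosage: np.ndarray, working_correlation, max_iter, tol, bias_correction):
    d = np.asarray(dosage, dtype=float)
    if np.isnan(d).any():
        d = np.where(np.isnan(d), np.nanmean(d), d)
    if np.nanstd(d) == 0:
        raise ValueError("monomorphic in analysis sample")
    g = d[design.subj_of_row]
    X = np.column_stack(
        [design.X_base, g, g * design.age_c, g * design.s1, g * design.s2]
    )
    names = design.base_names + ["g", "g_x_age", "g_x_s1", "g_x_s2"]
    fit = fit_gee(
        design.y,
        X,
        design.groups,
        working_correlation=working_correlation,
        max_iter=max_iter,
        tol=tol,
        exog_names=names,
        bias_correction=bias_correction,
        _layout=(design.starts, design.sizes),
    )
    return fit, d


def scan_variant(
    design: ScanDesign,
    dosage: np.ndarray,
    working_correlation: str = "exchangeable",
    max_iter: int = 50,
    tol: float = 1e-8,
    joint_test: bool = True,
    bias_correction: str | None = "mancl-derouen",
) -> dict:
    """Fit one variant's four-parameter trajectory model.

    Returns a flat record with per-block beta / robust SE / p for the
    genotype main effect and its age, slope-1 and slope-2 interactions.
    Robust SEs use the Mancl-DeRouen bias-corrected sandwich by default,
    which keeps Wald tests calibrated at a few hundred clusters; pass
    ``bias_correction=None`` for the classic uncorrected estimator.
    Raises on a monomorphic dosage; non-convergence is flagged, not fatal.
    """
    fit, d = _variant_fit(design, dosage, working_correlation, max_iter, tol, bias_correction)
    p_base = len(design.base_names)
    z, p = fit.wald()
    rec = {"eaf": float(np.mean(d) / 2.0), "converged": fit.converged, "n_iter": fit.n_iter}
    for k, block in enumerate(PARAM_BLOCKS):
        j = p_base + k
        rec[f"{block}_beta"] = float(fit.beta[j])
        rec[f"{block}_se"] = float(fit.robust_se[j])
        rec[f"{block}_p"] = float(p[j])
    if joint_test:
        idx = np.arange(p_base, p_base + 4)
        bg = fit.beta[idx]
        cov = fit.robust_cov[np.ix_(idx, idx)]
        stat = float(bg @ np.linalg.solve(cov, bg))
        rec["joint_chi2"] = stat
        rec["joint_p"] = float(stats.chi2.sf(stat, 4))
    return rec


def run_scan(
    cohort: CohortData,
    outcome: pd.DataFrame,
    variant_ids=None,
    pcs: np.ndarray | None = None,
    risk_variant_ids=(),
    knot_days: float = 365.0,
    age_ref: float | None = None,
    working_correlation: str = "exchangeable",
    threshold: float = GENOME_WIDE_P,
    adjust_lifestyle: bool = False,
    joint_test: bool = False,
    bias_correction: str | None = "mancl-derouen",
):
    """Scan every (QC-passing) variant against one outcome's trajectory.

    Returns ``(records, summary)``: a DataFrame with one row per tested
    variant in GWAS-summary layout, and a :class:`ScanSummary` carrying
    per-parameter genomic-inflation lambdas. Per-variant failures are
    logged and skipped, never raised.
    """
    design = build_scan_design(
        cohort,
        outcome,
        pcs=pcs,
        risk_variant_ids=risk_variant_ids,
        knot_days=knot_days,
        age_ref=age_ref,
        adjust_lifestyle=adjust_lifestyle,
    )
    meta = cohort.variant_meta
    if variant_ids is None:
        variant_ids = meta["variant_id"].tolist()
    # covariate loci cannot be scanned against themselves (exact collinearity)
    variant_ids = [v for v in variant_ids if v not in set(risk_variant_ids)]
    pos_of = pd.Series(meta.index.to_numpy(), index=meta["variant_id"])

    records, skipped = [], []
    for vid in variant_ids:
        j = int(pos_of[vid])
        try:
            rec = scan_variant(
                design,
                cohort.dosages[:, j],
                working_correlation=working_correlation,
                joint_test=joint_test,
                bias_correction=bias_correction,
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("variant %s skipped: %s", vid, err)
            skipped.append((vid, str(err)))
            continue
        row = meta.iloc[j]
        rec.update(
            variant_id=vid,
            chrom=row["chrom"],
            pos=int(row["pos"]),
            effect_allele=row["alt"],
            other_allele=row["ref"],
        )
        records.append(rec)

    lead = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]
    table = pd.DataFrame(records)
    if len(table):
        table = table[lead + [c for c in table.columns if c not in lead]]
    lambdas = {
        block: genomic_lambda(p=table[f"{block}_p"].to_numpy()) if len(table) else np.nan
        for block in PARAM_BLOCKS
    }
    sig = 0
    if len(table):
        sig = int(
            (table[[f"{b}_p" for b in PARAM_BLOCKS]].min(axis=1) < threshold).sum()
        )
    summary = ScanSummary(
        lambdas=lambdas,
        n_tested=len(table),
        n_converged=int(table["converged"].sum()) if len(table) else 0,
        n_significant=sig,
        n_skipped=len(skipped),
        threshold=threshold,
        skipped=skipped,
    )
    return table, summary


def genomic_lambda(p=None, chi2=None) -> float:
    """Genomic-control lambda: median observed chi2(1) over its null median."""
    if chi2 is None:
        if p is None:
            raise ValueError("provide p-values or chi-square statistics")
        p = np.asarray(p, dtype=float)
        p = p[~np.isnan(p)]
        if p.size == 0:
            raise ValueError("empty p-value vector")
        chi2 = stats.chi2.isf(p, 1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty chi-square vector")
    return float(np.median(chi2) / _CHI2_NULL_MEDIAN)


def _ld_r2(dosages: np.ndarray, j: int, candidates: np.ndarray) -> np.ndarray:
    x = dosages[:, j]
    Y = dosages[:, candidates]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    num = xc @ Yc
    den = np.sqrt((xc @ xc) * np.sum(Yc * Yc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r**2


def clump(
    records: pd.DataFrame,
    parameter: str,
    dosages: np.ndarray,
    variant_meta: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
):
    """Greedy LD clumping of significant variants for one parameter.

    Significant variants are ranked by ascending p (ties by chrom, pos);
    the best unassigned variant becomes an index and absorbs every
    still-unassigned significant variant on the same chromosome within
    ``window_kb`` whose pairwise r2 (squared Pearson correlation of
    dosages) reaches ``r2_threshold``. Returns ``(index_ids,
    assignments)`` where assignments maps each significant variant to its
    clump index.
    """
    pcol = f"{parameter}_p" if not parameter.endswith("_p") else parameter
    sig = records.loc[records[pcol] < p_threshold].copy()
    if sig.empty:
        return [], pd.DataFrame(columns=["variant_id", "index_id", "r2_with_index"])
    col_of = pd.Series(variant_meta.index.to_numpy(), index=variant_meta["variant_id"])
    sig["_col"] = col_of.loc[sig["variant_id"]].to_numpy()
    sig["pos"] = sig["pos"].astype(np.int64)
    sig = sig.sort_values([pcol, "chrom", "pos"], kind="stable").reset_index(drop=True)

    assigned = np.zeros(len(sig), dtype=bool)
    index_ids, rows = [], []
    window = window_kb * 1000.0
    for i in range(len(sig)):
        if assigned[i]:
            continue
        assigned[i] = True
        idx_id = sig.at[i, "variant_id"]
        index_ids.append(idx_id)
        rows.append({"variant_id": idx_id, "index_id": idx_id, "r2_with_index": 1.0})
        near = np.flatnonzero(
            (~assigned)
            & (sig["chrom"].to_numpy() == sig.at[i, "chrom"])
            & (np.abs(sig["pos"].to_numpy() - sig.at[i, "pos"]) <= window)
        )
        if near.size:
            r2 = _ld_r2(dosages, int(sig.at[i, "_col"]), sig["_col"].to_numpy()[near])
            for k, r2k in zip(near, r2):
                if r2k >= r2_threshold:
                    assigned[k] = True
                    rows.append(
                        {
                            "variant_id": sig.at[int(k), "variant_id"],
                            "index_id": idx_id,
                            "r2_with_index": float(r2k),
                        }
                    )
    return index_ids, pd.DataFrame(rows)


def lookup_variants(
    records: pd.DataFrame, external: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Look up externally reported variants in the scan results.

    ``external`` needs columns variant_id and effect_allele (optional
    beta). Betas are harmonised to the external effect allele: when it
    matches the scan's other (non-effect) allele, scan betas are negated;
    when it matches neither allele the row is flagged unmatched. Variants
    absent from the scan get a ``tested = False`` row. A Bonferroni
    threshold of ``alpha / (n_external * 4)`` flags survivors.
    """
    n_tests = max(len(external), 1) * len(PARAM_BLOCKS)
    bonf = alpha / n_tests
    rec = records.set_index("variant_id")
    out = []
    for row in external.itertuples(index=False):
        entry = {
            "variant_id": row.variant_id,
            "external_effect_allele": row.effect_allele,
            "external_beta": getattr(row, "beta", np.nan),
            "bonferroni_threshold": bonf,
        }
        if row.variant_id not in rec.index:
            entry.update(tested=False, note="not tested")
            out.append(entry)
            continue
        r = rec.loc[row.variant_id]
        if row.effect_allele == r["effect_allele"]:
            sign = 1.0
        elif row.effect_allele == r["other_allele"]:
            sign = -1.0
        else:
            entry.update(tested=False, note="allele mismatch")
            out.append(entry)
            continue
        entry.update(tested=True, note="")
        survives = False
        for block in PARAM_BLOCKS:
            entry[f"{block}_beta"] = sign * r[f"{block}_beta"]
            entry[f"{block}_se"] = r[f"{block}_se"]
            entry[f"{block}_p"] = r[f"{block}_p"]
            survives = survives or r[f"{block}_p"] < bonf
        entry["significant_bonferroni"] = survives
        out.append(entry)
    return pd.DataFrame(out)


def qq_table(p, n_points: int | None = None) -> pd.DataFrame:
    """Expected-vs-observed -log10 p table for a QQ plot."""
    p = np.sort(np.asarray(p, dtype=float))
    p = p[~np.isnan(p)]
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    df = pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(np.maximum(p, 1e-300))}
    )
    if n_points is not None and n > n_points:
        keep = np.unique(np.geomspace(1, n, n_points).astype(int) - 1)
        df = df.iloc[keep].reset_index(drop=True)
    return df


def manhattan_table(records: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """chrom / pos / -log10 p table for a Manhattan plot."""
    pcol = f"{parameter}_p"
    return pd.DataFrame(
        {
            "chrom": records["chrom"],
            "pos": records["pos"],
            "neglog10_p": -np.log10(np.maximum(records[pcol].to_numpy(dtype=float), 1e-300)),
            "variant_id": records["variant_id"],
        }
    )
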