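"""End-to-end orchestration: simulate -> prep -> QC -> selection check ->
scan -> clump -> PRS, as one reproducible, configured run.

Every stochastic stage draws from a substream derived deterministically
from the run seed, so a rerun with the same configuration reproduces all
numeric outputs. Each stage writes its tables into the run directory and
a provenance JSON records the configuration hash, seed and library
versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io
from .models import GEEFit, LMMFit
from .phenotypes import (
    DEFAULT_DOMAIN_MAP,
    apply_standardizer,
    composite_score,
    domain_score,
    fit_standardizer,
)
from .prs import compute_prs, select_and_align, test_prs_trajectory
from .qc import QCThresholds, filter_variants, genotype_pca, variant_qc_table
from .scan import GENOME_WIDE_P, PARAM_BLOCKS, clump, run_scan
from .selection import flag_selection_loci, selection_report
from .simulate import CohortData, SimulationConfig, TrueEffects, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "sensitivity_compare", "load_config", "outcome_tables"]

OUTCOMES = ("global", "attention", "executive", "memory", "learning", "language")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` (generate a cohort) or ``paths`` (vcf,
    phenotypes, covariates of a supplied cohort) must be set. Threshold
    defaults are the conventional ones: genome-wide p 5e-8, EMAC 200,
    MAF 1%, imputation r2 0.7, HWE p 1e-8, call rate 95%.
    """

    simulation: SimulationConfig | None = None
    paths: dict | None = None
    outcomes: tuple = OUTCOMES
    knot_days: float = 365.0
    genome_wide_p: float = GENOME_WIDE_P
    qc: QCThresholds = field(default_factory=QCThresholds)
    working_correlation: str = "exchangeable"
    n_pcs: int = 5
    pca_thin_step: int = 1
    risk_variant_ids: tuple = ("var0001", "var0002")
    clump_r2: float = 0.1
    clump_window_kb: float = 1000.0
    prs_weights_path: str | None = None
    seed: int = 0
    hwe_on_dosages: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    qc = raw.pop("qc", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        sim["allele_freq_range"] = tuple(sim.get("allele_freq_range", (0.05, 0.5)))
        sim["age_range_years"] = tuple(sim.get("age_range_years", (65.0, 83.0)))
        cfg.simulation = SimulationConfig(**sim)
    if qc is not None:
        cfg.qc = QCThresholds(**qc)
    if cfg.outcomes is not None:
        cfg.outcomes = tuple(cfg.outcomes)
    cfg.risk_variant_ids = tuple(cfg.risk_variant_ids)
    return cfg


def outcome_tables(phenotypes: pd.DataFrame, domain_map=None):
    """Standardise raw scores and build the six outcome z-tables.

    Returns ``(standardizer, {outcome_name: long z rows})`` with domain
    scores for the five domains and their composite under ``global``.
    """
    std = fit_standardizer(phenotypes)
    z = apply_standardizer(std, phenotypes)
    domains = domain_score(z, domain_map or DEFAULT_DOMAIN_MAP)
    comp = composite_score(domains)
    tables = {"global": comp}
    for name in (domain_map or DEFAULT_DOMAIN_MAP):
        tables[name] = domains.loc[domains["domain"] == name].reset_index(drop=True)
    return std, tables


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _synthetic_weights(cohort: CohortData, rng: np.random.Generator, n_hits: int = 20) -> pd.DataFrame:
    """A stand-in external weights table drawn from the cohort's own panel.

    Synthetic: picks variants at random, assigns modest published-scale
    effect sizes and genome-wide significant source p-values. Used only
    when no real weights file is configured.
    """
    meta = cohort.variant_meta
    pick = rng.choice(len(meta), size=min(n_hits, len(meta)), replace=False)
    rows = meta.iloc[pick]
    return pd.DataFrame(
        {
            "variant_id": rows["variant_id"].to_numpy(),
            "chrom": rows["chrom"].to_numpy(),
            "pos": rows["pos"].to_numpy(),
            "effect_allele": rows["alt"].to_numpy(),
            "other_allele": rows["ref"].to_numpy(),
            "beta": rng.normal(0.0, 0.03, size=len(rows)).round(4),
            "p": 10.0 ** rng.uniform(-30, -8, size=len(rows)),
        }
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns a manifest of result objects and paths.

    Stage failures raise with the stage name in the message. The run
    directory receives: cohort files, z-score tables, the QC exclusion
    ledger, the selection report, one summary-statistics TSV per outcome,
    clump tables, PRS association tables and ``provenance.json``.
    """
    t0 = time.time()
    outdir = Path(outdir)
    os.makedirs(outdir, exist_ok=True)
    seedseq = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in seedseq.spawn(4)]
    manifest: dict = {"outdir": str(outdir), "stages": {}}

    def stage(name):
        manifest["stages"][name] = round(time.time() - t0, 2)
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    # -- stage: cohort ------------------------------------------------------
    if config.simulation is not None:
        cohort, inclusion = simulate_cohort(
            config.simulation, TrueEffects.null(config.risk_variant_ids), rng=streams[0]
        )
        cohort_io.write_cohort(cohort, outdir, prefix="cohort")
        inclusion.to_csv(outdir / "inclusion_log.tsv", sep="\t", index=False)
    elif config.paths:
        for key in ("vcf", "phenotypes", "covariates"):
            if key not in config.paths:
                raise ValueError(f"stage cohort: missing path entry {key!r}")
            if not Path(config.paths[key]).exists():
                raise FileNotFoundError(
                    f"stage cohort: input file not found: {config.paths[key]}"
                )
        cohort = cohort_io.read_cohort(
            config.paths["vcf"], config.paths["phenotypes"], config.paths["covariates"]
        )
    else:
        raise ValueError("stage cohort: need either a simulation config or input paths")
    cohort.validate()
    stage("cohort")

    # -- stage: phenotypes --------------------------------------------------
    std, tables = outcome_tables(cohort.phenotypes)
    for name, tab in tables.items():
        tab.to_csv(outdir / f"z_{name}.tsv", sep="\t", index=False)
    stage("phenotypes")

    # -- stage: qc ----------------------------------------------------------
    qc_tab = variant_qc_table(
        cohort.dosages, cohort.variant_meta, hwe_from_dosages=config.hwe_on_dosages
    )
    kept, ledger = filter_variants(qc_tab, config.qc)
    if not kept:
        raise ValueError(
            "stage qc: every variant excluded; thresholds (notably EMAC "
            f"> {config.qc.emac:g}) may be out of scale for N={cohort.n_subjects}"
        )
    # risk loci stay available as covariates regardless of QC fate
    qc_tab.to_csv(outdir / "variant_qc.tsv", sep="\t", index=False)
    ledger.to_csv(outdir / "qc_exclusions.tsv", sep="\t", index=False)
    stage("qc")

    # -- stage: selection check --------------------------------------------
    report = selection_report(cohort, threshold=config.genome_wide_p, variant_ids=kept)
    report.table.to_csv(outdir / "selection_report.tsv", sep="\t", index=False)
    covariate_loci = flag_selection_loci(report, list(config.risk_variant_ids))
    stage("selection")

    # -- stage: PCA ---------------------------------------------------------
    kept_cols = [cohort.variant_index(v) for v in kept]
    pcs, explained = genotype_pca(
        cohort.dosages[:, kept_cols], k=config.n_pcs, thin_step=config.pca_thin_step
    )
    stage("pca")

    # -- stage: scan + clump -----------------------------------------------
    scan_results, summaries, clumps = {}, {}, {}
    for name in config.outcomes:
        records, summary = run_scan(
            cohort,
            tables[name],
            variant_ids=kept,
            pcs=pcs,
            risk_variant_ids=covariate_loci,
            knot_days=config.knot_days,
            working_correlation=config.working_correlation,
            threshold=config.genome_wide_p,
        )
        records.to_csv(outdir / f"scan_{name}.tsv", sep="\t", index=False)
        scan_results[name] = records
        summaries[name] = summary
        for block in ("slope1", "slope2"):
            index_ids, assign = clump(
                records,
                block,
                cohort.dosages,
                cohort.variant_meta,
                p_threshold=config.genome_wide_p,
                r2_threshold=config.clump_r2,
                window_kb=config.clump_window_kb,
            )
            if index_ids:
                assign.to_csv(outdir / f"clump_{name}_{block}.tsv", sep="\t", index=False)
            clumps[(name, block)] = index_ids
    stage("scan")

    # -- stage: prs ---------------------------------------------------------
    if config.prs_weights_path:
        weights = pd.read_csv(config.prs_weights_path, sep="\t")
    else:
        weights = _synthetic_weights(cohort, streams[2])
        weights.to_csv(outdir / "synthetic_weights.tsv", sep="\t", index=False)
    prs_rows = []
    model = select_and_align(
        weights, cohort, trait="trait", p_threshold=config.genome_wide_p,
        r2_threshold=config.clump_r2, window_kb=config.clump_window_kb,
    )
    model.ledger.to_csv(outdir / "prs_ledger.tsv", sep="\t", index=False)
    score = compute_prs(model, cohort)
    for name in config.outcomes:
        assoc = test_prs_trajectory(
            cohort,
            tables[name],
            score,
            trait=model.trait,
            outcome_name=name,
            pcs=pcs,
            risk_variant_ids=covariate_loci,
            knot_days=config.knot_days,
        )
        prs_rows.append(assoc.as_row())
    prs_table = pd.DataFrame(prs_rows)
    prs_table.to_csv(outdir / "prs_associations.tsv", sep="\t", index=False)
    stage("prs")

    # -- provenance ---------------------------------------------------------
    import scipy
    import statsmodels

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "n_subjects": int(cohort.n_subjects),
        "n_variants_kept": len(kept),
        "lambdas": {k: v.lambdas for k, v in summaries.items()},
        "selection_flagged": report.flagged,
        "stage_seconds": manifest["stages"],
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    manifest.update(
        cohort=cohort,
        standardizer=std,
        outcome_tables=tables,
        qc_kept=kept,
        qc_ledger=ledger,
        selection=report,
        pcs=pcs,
        pca_explained=explained,
        scans=scan_results,
        summaries=summaries,
        clumps=clumps,
        prs_model=model,
        prs_table=prs_table,
        provenance=provenance,
    )
    return manifest


def sensitivity_compare(fit_full, fit_subset) -> pd.DataFrame:
    """Side-by-side coefficient comparison of two fits of the same model.

    Used to check that results on the full phenotyped sample and the
    genotyped subset agree. Raises when the two fits are parameterised
    differently.
    """
    for f in (fit_full, fit_subset):
        if not isinstance(f, (GEEFit, LMMFit)):
            raise TypeError("expected GEEFit or LMMFit")
    if list(fit_full.exog_names) != list(fit_subset.exog_names) or len(
        fit_full.beta
    ) != len(fit_subset.beta):
        raise ValueError("fits are parameterised differently; cannot compare")
    se_full = fit_full.robust_se if isinstance(fit_full, GEEFit) else fit_full.se
    diff = fit_full.beta - fit_subset.beta
    return pd.DataFrame(
        {
            "term": fit_full.exog_names or [f"b{i}" for i in range(len(diff))],
            "beta_full": fit_full.beta,
            "beta_subset": fit_subset.beta,
            "abs_diff": np.abs(diff),
            "diff_over_se": diff / se_full,
        }
    )
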