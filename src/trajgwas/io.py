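"""Cohort serialisation: dosage VCF (FORMAT/DS), phenotype and covariate TSVs.

The VCF writer emits a minimal VCF 4.2 with one ``DS`` (dosage) value per
sample, an ``R2`` INFO field carrying per-variant imputation quality, and
contig header lines; reading is done through cyvcf2 so the written files
stay interoperable with standard tooling. Dosages are printed with six
significant decimals, so a write/read round trip reproduces the matrix to
1e-6.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CohortData

__all__ = ["write_cohort", "read_cohort", "write_vcf", "read_vcf"]


def write_vcf(path, dosages: np.ndarray, subject_ids, variant_meta: pd.DataFrame) -> None:
    path = Path(path)
    chroms = []
    for c in variant_meta["chrom"].astype(str):
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=trajgwas\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality r-squared">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, subject_ids)) + "\n")
        for j, row in enumerate(variant_meta.itertuples(index=False)):
            ds = "\t".join(
                "." if np.isnan(d) else f"{d:.6f}".rstrip("0").rstrip(".")
                for d in dosages[:, j]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}\t.\t.\t"
                f"R2={row.imputation_r2:.6f}\tDS\t{ds}\n"
            )


def read_vcf(path):
    """Read a DS-format dosage VCF back into (dosages, subject_ids, variant_meta)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = np.asarray(vcf.samples)
    rows, meta = [], []
    for v in vcf:
        ds = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        rows.append(ds)
        r2 = v.INFO.get("R2")
        meta.append(
            {
                "variant_id": v.ID,
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "imputation_r2": float(r2) if r2 is not None else np.nan,
            }
        )
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    return np.column_stack(rows), subjects, pd.DataFrame(meta)


def write_cohort(cohort: CohortData, directory, prefix: str = "cohort") -> dict:
    """Write a cohort as VCF + phenotype TSV + covariate TSV; returns the paths."""
    if cohort.phenotypes is None or len(cohort.phenotypes) == 0:
        raise ValueError("cohort has an empty phenotype table; nothing to write")
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": directory / f"{prefix}.vcf",
        "phenotypes": directory / f"{prefix}.phenotypes.tsv",
        "covariates": directory / f"{prefix}.covariates.tsv",
    }
    write_vcf(paths["vcf"], cohort.dosages, cohort.subject_ids, cohort.variant_meta)
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    cohort.covariates.to_csv(paths["covariates"], sep="\t", index=False)
    return paths


def read_cohort(vcf_path, phenotype_path, covariate_path) -> CohortData:
    dosages, subjects, meta = read_vcf(vcf_path)
    phen = pd.read_csv(phenotype_path, sep="\t", dtype={"subject_id": str})
    covar = pd.read_csv(covariate_path, sep="\t", dtype={"subject_id": str})
    covar_ids = covar["subject_id"].to_numpy()
    if not np.array_equal(covar_ids, subjects):
        order = pd.Series(np.arange(len(covar_ids)), index=covar_ids)
        try:
            idx = order.loc[subjects].to_numpy()
        except KeyError as err:
            raise ValueError("covariate table does not cover all VCF samples") from err
        covar = covar.iloc[idx].reset_index(drop=True)
    cohort = CohortData(
        dosages=dosages,
        subject_ids=np.asarray(subjects, dtype=object),
        variant_meta=meta,
        covariates=covar,
        phenotypes=phen,
    )
    cohort.validate()
    return cohort
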