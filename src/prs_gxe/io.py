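"""File interfaces: VCF and TSV genotypes, base (GWAS weights) TSV, cohort
CSV, and result tables.

Genotype VCFs are written as plain-text VCF 4.2 with GT fields (missing
call ``./.``) and read back through cyvcf2; dosages count ALT alleles. The
base file follows the PRSice column convention
``SNP CHR BP A1 A2 BETA P`` (A1 = effect allele). All round-trips are
lossless for the supported fields.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, validate_weights
from .errors import ValidationError

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_base",
    "read_base",
    "write_cohort",
    "read_cohort",
]

log = logging.getLogger(__name__)

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}

BASE_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"]
_BASE_TO_INTERNAL = {
    "SNP": "snp",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "beta",
    "P": "p",
}

#: Column dictionary of the cohort CSV (fixed columns; visit-suffixed
#: families are matched by pattern).
COHORT_FIXED_COLUMNS = {
    "subject_id", "group", "recruitment", "age", "bmi", "parity", "smoking",
    "education_years", "prs_true_z", "prs_raw", "prs_z", "fg_pp12",
    "g2h_pp12", "physician_diabetes", "fibre_g", "fruit_veg_portions",
    "sat_fat_pct", "gwg_category", "pa_min_week", "tertile",
    "true_gdm", "true_early_gdm", "true_booking_gdm", "true_pp12_abnormal",
    "gdm", "early_gdm", "booking_gdm", "pp12_label", "pp12_abnormal",
    "hfii", "success_score", "success",
}
_COHORT_PATTERNS = (
    re.compile(r"^ogtt_t[12]_[012]h$"),
    re.compile(r"^(fg|insulin|hba1c|hba1c_mmol|homa_ir|homa_b)_(t[123]|pp6wk|pp6mo|pp12)$"),
    re.compile(r"^hfii_[a-z_]+$"),
)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCF with GT fields."""
    path = Path(path)
    contigs = list(dict.fromkeys(genotypes.variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=prs-gxe\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, v in genotypes.variants.iterrows():
            calls = [
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (ALT-allele counts, nan for ./.)."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{path}: variant {rec.ID} at {rec.CHROM}:{rec.POS} is not biallelic"
            )
        rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            a = [x for x in gt[:2] if x is not None and x >= 0]
            if len(a) == 2:
                col[i] = float(sum(a))
        dosage_cols.append(col)
    vcf.close()
    if not rows:
        raise ValidationError(f"{path}: no variant records")
    return GenotypeMatrix(
        dosages=np.column_stack(dosage_cols),
        samples=samples,
        variants=pd.DataFrame(rows),
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.dosages.tsv`` (sample x variant matrix, NA missing)
    and ``<prefix>.variants.tsv`` (metadata)."""
    prefix = Path(prefix)
    dpath = prefix.with_suffix(".dosages.tsv")
    vpath = prefix.with_suffix(".variants.tsv")
    mat = pd.DataFrame(
        genotypes.dosages, columns=genotypes.variants["id"], index=genotypes.samples
    )
    mat.index.name = "sample_id"
    mat.to_csv(dpath, sep="\t", na_rep="NA")
    genotypes.variants.to_csv(vpath, sep="\t", index=False)
    return dpath, vpath


def read_dosage_tsv(prefix: str | Path) -> GenotypeMatrix:
    """Read the pair written by :func:`write_dosage_tsv`."""
    prefix = Path(prefix)
    dpath = prefix.with_suffix(".dosages.tsv")
    vpath = prefix.with_suffix(".variants.tsv")
    for p in (dpath, vpath):
        if not p.exists():
            raise ValidationError(f"missing dosage file: {p}")
    mat = pd.read_csv(dpath, sep="\t", index_col="sample_id")
    variants = pd.read_csv(vpath, sep="\t", dtype={"chrom": str})
    if list(mat.columns) != list(variants["id"]):
        raise ValidationError("dosage matrix columns do not match the variant table")
    return GenotypeMatrix(
        dosages=mat.to_numpy(dtype=float),
        samples=[str(s) for s in mat.index],
        variants=variants,
    )


def write_base(weights: pd.DataFrame, path: str | Path) -> None:
    """Write GWAS weights in the tab-delimited base layout SNP CHR BP A1 A2 BETA P."""
    w = validate_weights(weights)
    out = pd.DataFrame(
        {ext: w[internal] for ext, internal in _BASE_TO_INTERNAL.items()}
    )
    out.to_csv(path, sep="\t", index=False)


def read_base(path: str | Path) -> pd.DataFrame:
    """Read a PRSice-style base file; malformed rows are reported by line number."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"base file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: base file lacks columns {missing}")
    for col in ("BP", "BETA", "P"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad]  # +2: header + 1-based
            raise ValidationError(f"{path}: non-numeric {col} on lines {lines}")
        df[col] = coerced
    internal = df.rename(columns=_BASE_TO_INTERNAL)[list(_BASE_TO_INTERNAL.values())]
    return validate_weights(internal)


def _known_cohort_column(name: str) -> bool:
    return name in COHORT_FIXED_COLUMNS or any(
        p.match(name) for p in _COHORT_PATTERNS
    )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read the cohort CSV; unknown columns are dropped with a warning."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if not _known_cohort_column(c)]
    if unknown:
        log.warning("cohort %s: ignoring unknown columns %s", path, unknown)
        df = df.drop(columns=unknown)
    if "subject_id" not in df.columns:
        raise ValidationError(f"{path}: cohort CSV lacks a subject_id column")
    return df
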