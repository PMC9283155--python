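"""Run orchestration: one config in, one reproducible results bundle out.

``run_pipeline`` chains quality control -> LD clumping -> polygenic scoring
-> phenotype derivation -> interaction analysis, writing every intermediate
artifact and a run report whose parameter echo is sufficient to reproduce
the run exactly.
"""

from __future__ import annotations

import json
import time
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import io as pio
from .clinical_phenotypes import derive_cohort_phenotypes
from .containers import GenotypeMatrix
from .errors import ComputationError, ModelFitError, ValidationError
from .genotype_qc import QCThresholds, apply_qc
from .gxe_analysis import (
    COVARIATE_SETS,
    assign_tertiles,
    fit_interaction_model,
    adjusted_occurrence,
    per_tertile_intervention_or,
)
from .ld_clumping import ClumpParams, clump
from .prs_score import PRSParams, align_alleles, compute_prs

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


def _package_version() -> str:
    try:
        return pkg_version("prs-gxe")
    except PackageNotFoundError:
        return "unknown"


class QCSection(BaseModel):
    min_maf: float = 0.05
    min_variant_call_rate: float = 0.9
    hwe_p_floor: float = 1e-4
    max_sample_missing: float = 0.10


class ClumpSection(BaseModel):
    p_index_threshold: float = 1.0
    r2_threshold: float = 0.5
    window_kb: float = 250.0


class PRSSection(BaseModel):
    p_threshold: float = 5e-8
    standardize: bool = True
    missing_policy: str = "mean_impute"
    ambiguous_policy: str = "exclude"


class RunConfig(BaseModel):
    """Declarative description of one pipeline run.

    ``genotypes`` may point at a ``.vcf`` or at a dosage-TSV prefix (the
    pair written by :func:`prs_gxe.io.write_dosage_tsv`).
    """

    genotypes: str
    base: str
    cohort: str
    out_dir: str
    qc: QCSection = Field(default_factory=QCSection)
    clump: ClumpSection = Field(default_factory=ClumpSection)
    prs: PRSSection = Field(default_factory=PRSSection)
    covariate_set: str = "age"
    outcome: str = "gdm"
    exclude_booking_gdm: bool = True
    seed: int = 0

    def validate_paths(self) -> None:
        for name in ("base", "cohort"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name} file does not exist: {p}")
        g = Path(self.genotypes)
        if not (
            g.exists()
            or g.with_suffix(".dosages.tsv").exists()
        ):
            raise ValidationError(f"genotypes not found: {g}")
        if self.covariate_set not in COVARIATE_SETS:
            raise ValidationError(
                f"unknown covariate_set {self.covariate_set!r}; "
                f"choose from {sorted(COVARIATE_SETS)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


class RunReport(BaseModel):
    """Stage-by-stage accounting of one run."""

    config: RunConfig
    software_version: str
    wall_time_s: float
    counts: dict[str, dict[str, int]]
    results: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))


def _load_genotypes(path: str) -> GenotypeMatrix:
    p = Path(path)
    if p.suffix == ".vcf":
        return pio.read_vcf(p)
    return pio.read_dosage_tsv(p)


def _or_entry(res, term: str) -> dict:
    o, lo, hi = res.odds_ratios[term]
    return {
        "or": o, "ci_low": lo, "ci_high": hi,
        "p": res.p_values[term], "n": res.n,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Any stage error aborts the run with the stage name prepended; artifacts
    of completed stages remain on disk. Reruns with the same config are
    bit-identical for the deterministic stages (everything after the inputs
    are fixed).
    """
    t0 = time.time()
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict[str, int]] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except (ValidationError, ComputationError):
                raise
            except Exception as e:  # annotate unexpected failures with stage
                raise ComputationError(f"stage {name!r} failed: {e}") from e
        return wrap

    genotypes = stage("load")(lambda: _load_genotypes(config.genotypes))
    weights = stage("load")(lambda: pio.read_base(config.base))
    cohort = stage("load")(lambda: pio.read_cohort(config.cohort))
    counts["input"] = {
        "samples": genotypes.n_samples,
        "variants": genotypes.n_variants,
        "cohort_rows": len(cohort),
    }

    qc_thresholds = QCThresholds(**config.qc.model_dump())
    clean, qc_report = stage("qc")(lambda: apply_qc(genotypes, qc_thresholds))
    qc_report.variants.to_csv(out_dir / "qc_variants.tsv", sep="\t", index=False)
    qc_report.samples.to_csv(out_dir / "qc_samples.tsv", sep="\t", index=False)
    counts["qc"] = {"samples": clean.n_samples, "variants": clean.n_variants}

    clump_params = ClumpParams(**config.clump.model_dump())
    weights_clean = weights[weights["snp"].isin(clean.variants["id"])].reset_index(
        drop=True
    )
    clumped = stage("clump")(lambda: clump(clean, weights_clean, clump_params))
    clumped.to_table().to_csv(out_dir / "clumped.tsv", sep="\t", index=False)
    index_weights = weights_clean[
        weights_clean["snp"].isin(clumped.index_variants)
    ].reset_index(drop=True)
    counts["clump"] = {"index_variants": len(clumped.index_variants)}

    prs_params = PRSParams(**config.prs.model_dump())
    aligned = stage("score")(lambda: align_alleles(clean, index_weights, prs_params))
    prs = stage("score")(lambda: compute_prs(clean, aligned, prs_params))
    scores = prs.to_frame()
    scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
    counts["score"] = {"variants_used": prs.n_variants_used, "samples": len(scores)}

    def merge_and_derive():
        merged = cohort.merge(
            scores.rename(columns={"raw": "prs_raw", "zscore": "prs_z"}),
            left_on="subject_id",
            right_on="sample_id",
            how="inner",
        ).drop(columns=["sample_id", "n_snps"])
        if merged.empty:
            raise ValidationError("no overlap between cohort subject_id and scored samples")
        return derive_cohort_phenotypes(merged)

    derived = stage("phenotype")(merge_and_derive)
    counts["phenotype"] = {"samples": len(derived)}

    def analyze():
        results: dict = {}
        tert = assign_tertiles(derived["prs_z"].to_numpy())
        derived["tertile"] = tert.labels
        results["tertile_sizes"] = tert.sizes
        covars = COVARIATE_SETS[config.covariate_set]
        exclude = config.exclude_booking_gdm and config.outcome == "gdm"
        inter = fit_interaction_model(
            derived,
            outcome=config.outcome,
            covariates=covars,
            exclude_booking=exclude,
        )
        results["interaction"] = {
            "coefficients": inter.coefficients,
            "p_interaction": inter.p_values["prs_x_group"],
            "or_interaction": _or_entry(inter, "prs_x_group"),
            "n": inter.n,
        }
        analysis_df = derived[derived["booking_gdm"] != 1] if exclude else derived
        tert_a = assign_tertiles(analysis_df["prs_z"].to_numpy())
        per_tert = per_tertile_intervention_or(
            analysis_df, tert_a, outcome=config.outcome, covariates=covars
        )
        results["per_tertile_or"] = {
            lab: _or_entry(res, "group") for lab, res in per_tert.items()
        }
        occ = adjusted_occurrence(
            analysis_df, tert_a, outcome=config.outcome, covariates=covars
        )
        results["adjusted_occurrence"] = occ.to_dict(orient="records")
        results["n_analysis"] = int(len(analysis_df))
        return results

    results = stage("analyze")(analyze)
    pio.write_cohort(derived, out_dir / "cohort_derived.csv")
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    counts["analyze"] = {"samples": results["n_analysis"]}

    report = RunReport(
        config=config,
        software_version=_package_version(),
        wall_time_s=time.time() - t0,
        counts=counts,
        results=results,
    )
    report.save(out_dir / "report.json")
    return report
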