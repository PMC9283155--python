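"""Variant- and sample-level genotype quality control.

Implements the standard PLINK-style filter set: per-sample missingness,
minor allele frequency, per-variant call rate, and the exact test of
Hardy-Weinberg proportions (conditional on allele counts, no mid-p
correction). Samples are filtered first so that every variant statistic is
computed on the surviving samples; the order is configurable in
:func:`apply_qc` callers by pre-subsetting if a different convention is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import NoDataSurvivesQCError, UndefinedStatisticError, ValidationError

__all__ = ["QCThresholds", "QCReport", "compute_maf", "hwe_exact_test", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds.

    A variant fails when its MAF is below ``min_maf``, its call rate is below
    ``min_variant_call_rate``, or its Hardy-Weinberg exact p-value is below
    ``hwe_p_floor``. A sample fails when its fraction of missing calls
    exceeds ``max_sample_missing`` (strictly greater than).
    """

    min_maf: float = 0.05
    min_variant_call_rate: float = 0.9
    hwe_p_floor: float = 1e-4
    max_sample_missing: float = 0.10

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_variant_call_rate", "hwe_p_floor", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Per-variant and per-sample QC statistics and filter outcomes.

    ``variants`` columns: id, maf, call_rate, hwe_p, passed, reason.
    ``samples`` columns: sample, missing_fraction, passed, reason.
    ``reason`` holds the first failing filter ("sample_missing", "maf",
    "call_rate", "hwe") or an empty string.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    n_samples_in: int = 0
    n_variants_in: int = 0

    @property
    def n_samples_out(self) -> int:
        return int(self.samples["passed"].sum())

    @property
    def n_variants_out(self) -> int:
        return int(self.variants["passed"].sum())


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one variant from its dosage vector.

    Missing calls (nan) are excluded; the frequency is
    ``min(f, 1 - f)`` with ``f = sum(dosage) / (2 * n_nonmissing)``.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedStatisticError("MAF undefined: all calls missing")
    f = float(d[ok].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose point probability does not exceed the
    observed one — the classic exact test as implemented in PLINK (no mid-p
    adjustment). Probabilities are computed by the stable ratio recurrence
    over heterozygote counts of matching parity.

    Returns 1.0 for a monomorphic table (only one configuration exists).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative genotype counts: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValidationError("empty genotype table")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # copies of the rarer allele
    if rare == 0 or rare == 2 * n:
        return 1.0

    # Heterozygote count shares the parity of the rare-allele count.
    het_values = np.arange(rare % 2, rare + 1, 2)
    # Start the recurrence at the mode to avoid under/overflow.
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    if mid > rare:
        mid -= 2

    probs = {mid: 1.0}
    # P(het-2)/P(het) = het*(het-1) / ((rare-het+2)*(2n-rare-het+2))
    het = mid
    p = 1.0
    while het >= 2:
        p *= het * (het - 1) / ((rare - het + 2.0) * (2 * n - rare - het + 2.0))
        het -= 2
        probs[het] = p
    het = mid
    p = 1.0
    while het <= rare - 2:
        p *= (rare - het) * (2 * n - rare - het) / ((het + 2.0) * (het + 1.0))
        het += 2
        probs[het] = p

    total = sum(probs.values())
    obs = probs[n_het]
    # Relative guard so mathematically tied configurations are always
    # included regardless of round-off in the recurrence.
    cutoff = obs * (1.0 + 1e-9)
    pval = sum(v for v in probs.values() if v <= cutoff) / total
    return min(1.0, pval)


def _genotype_counts(d: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(d)
    return (
        int((d[ok] == 0).sum()),
        int((d[ok] == 1).sum()),
        int((d[ok] == 2).sum()),
    )


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples, then variants; return the clean matrix and a report.

    Sample missingness is evaluated on the full variant panel; variant MAF,
    call rate and HWE are then computed on surviving samples only, so that a
    badly genotyped sample cannot fail an otherwise sound variant.
    """
    if genotypes.n_samples == 0 or genotypes.n_variants == 0:
        raise ValidationError("empty genotype matrix")

    miss_frac = np.isnan(genotypes.dosages).mean(axis=1)
    sample_pass = miss_frac <= thresholds.max_sample_missing
    sample_report = pd.DataFrame(
        {
            "sample": genotypes.samples,
            "missing_fraction": miss_frac,
            "passed": sample_pass,
            "reason": np.where(sample_pass, "", "sample_missing"),
        }
    )
    kept = genotypes.subset(sample_mask=sample_pass)
    if kept.n_samples == 0:
        raise NoDataSurvivesQCError("no sample survives the missingness filter")

    mafs, call_rates, hwe_ps, passed, reasons = [], [], [], [], []
    for j in range(kept.n_variants):
        d = kept.dosages[:, j]
        ok = ~np.isnan(d)
        call_rate = float(ok.mean())
        if ok.any():
            maf = compute_maf(d)
            hwe_p = hwe_exact_test(*_genotype_counts(d))
        else:
            maf, hwe_p = np.nan, 1.0
        fails = []
        if not np.isnan(maf) and maf < thresholds.min_maf:
            fails.append("maf")
        if call_rate < thresholds.min_variant_call_rate:
            fails.append("call_rate")
        if hwe_p < thresholds.hwe_p_floor:
            fails.append("hwe")
        if np.isnan(maf):
            fails.append("call_rate")  # all-missing: only the call rate is defined
        mafs.append(maf)
        call_rates.append(call_rate)
        hwe_ps.append(hwe_p)
        passed.append(not fails)
        reasons.append(fails[0] if fails else "")

    variant_report = pd.DataFrame(
        {
            "id": kept.variants["id"],
            "maf": mafs,
            "call_rate": call_rates,
            "hwe_p": hwe_ps,
            "passed": passed,
            "reason": reasons,
        }
    )
    out = kept.subset(variant_mask=np.asarray(passed, dtype=bool))
    if out.n_variants == 0:
        raise NoDataSurvivesQCError("no variant survives QC")
    report = QCReport(
        variants=variant_report,
        samples=sample_report,
        n_samples_in=genotypes.n_samples,
        n_variants_in=genotypes.n_variants,
    )
    return out, report
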