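"""Greedy p-value-ordered linkage-disequilibrium clumping.

Index variants are selected in ascending order of GWAS association p-value;
each index absorbs every not-yet-assigned variant on the same chromosome
within the base-pair window whose dosage r-squared with the index reaches
the threshold. r-squared is the squared Pearson correlation of unphased
dosages over pairwise-complete samples (the Rogers-Huff genotype
estimator), which tracks the haplotype r-squared closely for data in
Hardy-Weinberg proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, validate_weights
from .errors import UndefinedStatisticError, ValidationError

__all__ = ["ClumpParams", "ClumpResult", "estimate_r2", "clump"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpParams:
    """Clumping parameters: index p-value ceiling, r² threshold (inclusive),
    and window half-width in kb (index-to-candidate distance, inclusive)."""

    p_index_threshold: float = 1.0
    r2_threshold: float = 0.5
    window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_index_threshold <= 1.0:
            raise ValidationError("p_index_threshold must be in (0, 1]")
        if not 0.0 <= self.r2_threshold:
            raise ValidationError("r2_threshold must be non-negative")
        if self.window_kb <= 0:
            raise ValidationError("window_kb must be positive")


@dataclass
class ClumpResult:
    """Outcome of a clumping run.

    ``index_variants`` are retained ids in selection order; ``clumps`` maps
    each index id to the ids absorbed by it (excluding the index itself);
    ``r2`` records the r² used for each (index, member) assignment;
    ``unassigned`` lists variants that neither became an index (p above the
    index threshold) nor fell into any clump.
    """

    index_variants: list[str]
    clumps: dict[str, list[str]]
    r2: dict[tuple[str, str], float]
    unassigned: list[str] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        """PLINK ``.clumped``-like table: one row per index variant."""
        rows = []
        for idx in self.index_variants:
            members = self.clumps[idx]
            rows.append(
                {"SNP": idx, "TOTAL": len(members), "SP2": ",".join(members) or "NONE"}
            )
        return pd.DataFrame(rows, columns=["SNP", "TOTAL", "SP2"])


def estimate_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples. Raises
    :class:`UndefinedStatisticError` when fewer than two complete pairs
    remain or either variant is monomorphic in the overlap.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise UndefinedStatisticError("fewer than 2 pairwise-complete samples")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        raise UndefinedStatisticError("variant monomorphic in pairwise overlap")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def clump(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    params: ClumpParams = ClumpParams(),
) -> ClumpResult:
    """Greedy clumping of ``weights`` variants on the cohort's own LD.

    Variants are sorted by ascending p-value, ties broken by position then
    id, making the index set invariant to input ordering. A variant whose
    p-value exceeds ``p_index_threshold`` can join a clump but never found
    one. An undefined pairwise r² (monomorphic overlap) is treated as 0 and
    logged.
    """
    weights = validate_weights(weights)
    known = set(genotypes.variants["id"])
    missing = sorted(set(weights["snp"]) - known)
    if missing:
        raise ValidationError(f"weights variants absent from genotypes: {missing}")

    meta = genotypes.variants.set_index("id")
    w = weights.copy()
    w["pos"] = meta.loc[w["snp"], "pos"].to_numpy()
    w["chrom"] = meta.loc[w["snp"], "chrom"].to_numpy()
    order = w.sort_values(["p", "pos", "snp"], kind="stable")

    window_bp = params.window_kb * 1000.0
    assigned: set[str] = set()
    index_variants: list[str] = []
    clumps: dict[str, list[str]] = {}
    r2_used: dict[tuple[str, str], float] = {}

    for row in order.itertuples(index=False):
        if row.snp in assigned:
            continue
        if row.p > params.p_index_threshold:
            continue  # never an index
        assigned.add(row.snp)
        index_variants.append(row.snp)
        clumps[row.snp] = []
        j = genotypes.variant_index(row.snp)
        # Candidates: same chromosome, within the window, not yet assigned.
        cands = order[
            (order["chrom"] == row.chrom)
            & ((order["pos"] - row.pos).abs() <= window_bp)
            & ~order["snp"].isin(assigned)
        ]
        for cand in cands.itertuples(index=False):
            k = genotypes.variant_index(cand.snp)
            try:
                r2 = estimate_r2(genotypes.dosages[:, j], genotypes.dosages[:, k])
            except UndefinedStatisticError:
                log.warning("r2 undefined for (%s, %s); treated as 0", row.snp, cand.snp)
                r2 = 0.0
            if r2 >= params.r2_threshold:
                assigned.add(cand.snp)
                clumps[row.snp].append(cand.snp)
                r2_used[(row.snp, cand.snp)] = r2

    unassigned = [s for s in weights["snp"] if s not in assigned]
    return ClumpResult(
        index_variants=index_variants,
        clumps=clumps,
        r2=r2_used,
        unassigned=unassigned,
    )
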