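"""Weighted polygenic score with allele alignment and a p-value threshold.

The score for a sample is the sum over included variants of the GWAS effect
size times the dosage of the effect allele. Before scoring, each weight's
effect allele is matched to the allele the genotype file counts: same
allele — used as-is; the other allele — the dosage is reinterpreted as
``2 - d``; matching only after strand complementation — complemented first;
otherwise excluded. Strand-ambiguous palindromic variants (A/T, C/G) are
excluded by default because their orientation cannot be resolved from
alleles alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, validate_weights
from .errors import EmptyScoreError, ValidationError

__all__ = ["PRSParams", "AlignedWeights", "PRSResult", "align_alleles", "compute_prs"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class PRSParams:
    """Scoring parameters.

    ``p_threshold`` — GWAS p-value below which a variant is included
    (strict ``<``); ``standardize`` — also report the within-cohort z-score;
    ``missing_policy`` — ``mean_impute`` substitutes twice the effect-allele
    frequency for a missing dosage (so every sample is scored on the same
    variant set), ``omit`` drops the variant from that sample's sum;
    ``ambiguous_policy`` — handling of palindromic variants.
    """

    p_threshold: float = 5e-8
    standardize: bool = True
    missing_policy: Literal["mean_impute", "omit"] = "mean_impute"
    ambiguous_policy: Literal["exclude", "keep"] = "exclude"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValidationError("p_threshold must be in (0, 1]")
        if self.missing_policy not in ("mean_impute", "omit"):
            raise ValidationError(f"unknown missing_policy {self.missing_policy!r}")
        if self.ambiguous_policy not in ("exclude", "keep"):
            raise ValidationError(f"unknown ambiguous_policy {self.ambiguous_policy!r}")


@dataclass
class AlignedWeights:
    """Weights after allele alignment.

    ``table`` keeps the original columns plus ``flipped`` (effect allele is
    the genotype's non-counted allele, so effect dosage is ``2 - d``);
    ``exclusions`` records dropped variants with a ``reason`` column
    (``ambiguous``, ``allele_mismatch``, ``missing_genotype``).
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame


@dataclass
class PRSResult:
    """Per-sample scores plus provenance.

    ``raw`` is the weighted dosage sum; ``zscore`` the within-cohort
    standardization of ``raw`` (mean 0, SD 1 with the n-1 denominator);
    ``n_variants_used`` counts scored variants; ``excluded`` carries over
    the alignment/threshold exclusion log.
    """

    samples: list[str]
    raw: np.ndarray
    zscore: np.ndarray | None
    n_variants_used: int
    excluded: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.samples, "raw": self.raw})
        if self.zscore is not None:
            out["zscore"] = self.zscore
        out["n_snps"] = self.n_variants_used
        return out


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC


def align_alleles(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    params: PRSParams = PRSParams(),
) -> AlignedWeights:
    """Match each weight's effect allele to the genotype's counted allele."""
    weights = validate_weights(weights)
    meta = genotypes.variants.set_index("id")
    kept_rows, flipped, excl_rows = [], [], []

    for row in weights.itertuples(index=False):
        if row.snp not in meta.index:
            excl_rows.append({"snp": row.snp, "reason": "missing_genotype"})
            continue
        a1, a2 = str(row.effect_allele).upper(), str(row.other_allele).upper()
        ref = str(meta.at[row.snp, "ref"]).upper()
        alt = str(meta.at[row.snp, "alt"]).upper()
        if _is_palindromic(a1, a2) and params.ambiguous_policy == "exclude":
            excl_rows.append({"snp": row.snp, "reason": "ambiguous"})
            continue
        pair, target = {a1, a2}, {ref, alt}
        if pair == target:
            eff = a1
        elif {_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)} == target:
            eff = _COMPLEMENT[a1]
        else:
            excl_rows.append({"snp": row.snp, "reason": "allele_mismatch"})
            continue
        kept_rows.append(row._asdict())
        flipped.append(eff == ref)  # effect allele is the non-counted one

    table = pd.DataFrame(kept_rows, columns=list(weights.columns))
    table["flipped"] = pd.Series(flipped, dtype=bool)
    exclusions = pd.DataFrame(excl_rows, columns=["snp", "reason"])
    return AlignedWeights(table=table, exclusions=exclusions)


def compute_prs(
    genotypes: GenotypeMatrix,
    aligned: AlignedWeights | pd.DataFrame,
    params: PRSParams = PRSParams(),
) -> PRSResult:
    """Score every sample: ``raw = sum beta * effect-allele dosage``.

    Only variants with GWAS ``p < p_threshold`` contribute. Missing dosages
    are mean-imputed with twice the cohort effect-allele frequency (or the
    variant is omitted from that sample under ``omit``).
    """
    if isinstance(aligned, AlignedWeights):
        table, excl = aligned.table, aligned.exclusions.copy()
    else:
        table, excl = aligned, pd.DataFrame(columns=["snp", "reason"])
    if "flipped" not in table.columns:
        raise ValidationError("weights are not aligned: run align_alleles first")

    below = table["p"] < params.p_threshold
    thresholded = table.loc[~below, ["snp"]].assign(reason="p_threshold")
    excl = pd.concat([excl, thresholded], ignore_index=True)
    use = table.loc[below]
    if use.empty:
        raise EmptyScoreError(
            f"no variant passes p < {params.p_threshold}; score would be empty"
        )

    cols = [genotypes.variant_index(s) for s in use["snp"]]
    d = genotypes.dosages[:, cols]
    flip = use["flipped"].to_numpy()
    eff = np.where(flip, 2.0 - d, d)  # effect-allele dosage; nan propagates

    betas = use["beta"].to_numpy(dtype=float)
    if params.missing_policy == "mean_impute":
        eaf = np.nanmean(eff, axis=0) / 2.0  # cohort effect-allele frequency
        eff = np.where(np.isnan(eff), 2.0 * eaf, eff)
        raw = eff @ betas
    else:  # omit: per-sample sum over the variant's non-missing calls
        raw = np.nansum(eff * betas, axis=1)

    zscore = None
    if params.standardize:
        sd = np.std(raw, ddof=1)
        if sd == 0.0:
            raise EmptyScoreError("score is constant across samples; z-score undefined")
        zscore = (raw - raw.mean()) / sd

    return PRSResult(
        samples=list(genotypes.samples),
        raw=raw,
        zscore=zscore,
        n_variants_used=int(len(use)),
        excluded=excl,
    )
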