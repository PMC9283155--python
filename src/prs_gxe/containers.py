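"""In-memory containers shared across the pipeline stages.

Genotypes are held as a dense samples x variants dosage matrix (count of the
ALT allele: 0, 1, 2, with ``nan`` for a missing call) next to a variant
metadata table. GWAS summary statistics ("base" weights) and the cohort
phenotype table are plain :class:`pandas.DataFrame` objects with documented
column contracts, validated by the helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Required columns of a variant metadata table.
VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt")

#: Required columns of a GWAS weights ("base") table.
WEIGHT_COLUMNS = ("snp", "chrom", "pos", "effect_allele", "other_allele", "beta", "p")


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix plus variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array; entries in ``{0, 1, 2}`` or
        ``nan`` for a missing call. Dosage counts copies of the ALT allele.
    samples
        Sample identifiers, one per row.
    variants
        Metadata table with columns ``id, chrom, pos, ref, alt`` (1-based
        positions, as in VCF), one row per dosage column.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = list(self.samples)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape[0] != len(self.samples):
            raise ValidationError(
                f"{len(self.samples)} sample ids but {self.dosages.shape[0]} dosage rows"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValidationError(f"variant table lacks columns: {missing_cols}")
        if self.dosages.shape[1] != len(self.variants):
            raise ValidationError(
                f"{len(self.variants)} variants but {self.dosages.shape[1]} dosage columns"
            )
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate variant ids: {dups}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be 0, 1, 2 or nan")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if idx.size == 0:
            raise KeyError(variant_id)
        return int(idx[0])

    def subset(
        self,
        sample_mask: np.ndarray | Sequence[bool] | None = None,
        variant_mask: np.ndarray | Sequence[bool] | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the masked samples / variants."""
        smask = (
            np.ones(self.n_samples, dtype=bool)
            if sample_mask is None
            else np.asarray(sample_mask, dtype=bool)
        )
        vmask = (
            np.ones(self.n_variants, dtype=bool)
            if variant_mask is None
            else np.asarray(variant_mask, dtype=bool)
        )
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(smask, vmask)].copy(),
            samples=[s for s, keep in zip(self.samples, smask) if keep],
            variants=self.variants.loc[vmask].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), list(self.samples), self.variants.copy()
        )

    def __eq__(self, other: object) -> bool:  # byte-identical comparison
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants.equals(other.variants)
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Validate a GWAS weights table and return it with a clean index.

    Raises :class:`ValidationError` on missing columns or duplicate SNP ids
    (a duplicated id would make allele alignment ambiguous).
    """
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValidationError(f"weights table lacks columns: {missing}")
    if weights["snp"].duplicated().any():
        dups = sorted(weights.loc[weights["snp"].duplicated(), "snp"].unique())
        raise ValidationError(f"duplicate SNP ids in weights: {dups}")
    bad_p = weights["p"][(weights["p"] <= 0) | (weights["p"] > 1)]
    if len(bad_p):
        raise ValidationError("weights p-values must lie in (0, 1]")
    return weights.reset_index(drop=True)
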