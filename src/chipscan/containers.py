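"""Shared in-memory containers.

The pipeline moves three kinds of tabular data around: genotype dosages,
eQTL summary statistics, and per-sample phenotype/score tables.  Summary
statistics and phenotypes are plain :class:`pandas.DataFrame` objects with
documented column contracts (see :mod:`chipscan.io`); dosages get a thin
wrapper so that the variant metadata (position, counted allele) travels
with the numeric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of the variant metadata table of a DosageMatrix.
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "counted_allele", "other_allele"]


@dataclass
class DosageMatrix:
    """Individuals x variants allele-dosage matrix.

    Parameters
    ----------
    sample_ids
        Length ``n_samples`` identifiers, unique.
    variants
        DataFrame with columns ``variant_id, chrom, pos, counted_allele,
        other_allele`` (one row per column of ``values``).  ``counted_allele``
        is the allele whose copies the dosage counts.
    values
        ``(n_samples, n_variants)`` float array with entries in ``[0, 2]``;
        ``NaN`` marks a missing dosage.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dosage values must be a 2-D array")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicated variant ids: {dups[:5]}")
        self.variants = self.variants.reset_index(drop=True)
        self._index = {v: j for j, v in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def column_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in dosage matrix") from None

    def dosage(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant (view, do not mutate)."""
        return self.values[:, self.column_index(variant_id)]

    def subset_variants(self, variant_ids: list[str]) -> "DosageMatrix":
        idx = [self.column_index(v) for v in variant_ids]
        return DosageMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            values=self.values[:, idx].copy(),
        )
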