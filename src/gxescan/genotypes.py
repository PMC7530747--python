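"""In-memory genotype container used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages (subjects x variants) plus variant metadata.

    ``dosages`` is a float array with values in [0, 2]; missing calls are
    NaN. ``variants`` has one row per column of ``dosages`` with at least
    variant_id, chrom, pos (1-based), ref, alt; an optional
    ``imputation_r2`` column carries imputation quality.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if self.dosages.shape != (len(self.subject_ids), len(self.variants)):
            raise ValueError(
                f"shape mismatch: dosages {self.dosages.shape} vs "
                f"{len(self.subject_ids)} subjects x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variants["variant_id"].to_numpy() == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant not found: {variant_id}")
        return int(idx[0])

    def dosage(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.variants.loc[mask].reset_index(drop=True),
            self.subject_ids,
        )

    def subset_subjects(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[mask, :], self.variants.copy(), self.subject_ids[mask]
        )

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.alt_allele_frequency()
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)
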