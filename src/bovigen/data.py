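"""In-memory containers for genotypes and relationship matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

MAP_COLUMNS = ("snp_id", "chrom", "pos")


@dataclass
class GenotypeMatrix:
    """Coded allele dosages for n animals at M biallelic SNPs.

    ``dosages`` is an n x M float array with entries in {0, 1, 2} and NaN for
    missing calls; columns follow ``snp_map`` (snp_id, chrom, pos sorted in
    ascending 1-based map order within chromosome).
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    animal_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D (animals x SNPs) array")
        if self.dosages.shape[0] != len(self.animal_ids):
            raise DataError(
                f"{self.dosages.shape[0]} dosage rows but "
                f"{len(self.animal_ids)} animal ids"
            )
        if self.dosages.shape[1] != len(self.snp_map):
            raise DataError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.snp_map)} SNPs in map"
            )
        missing = [c for c in MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise DataError(f"snp_map lacks columns: {missing}")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def allele_freqs(self) -> np.ndarray:
        """Observed coded-allele frequency per SNP, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            snp_map=self.snp_map.iloc[index].reset_index(drop=True),
            animal_ids=self.animal_ids,
        )

    def subset_animals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            snp_map=self.snp_map,
            animal_ids=self.animal_ids[index],
        )


@dataclass
class RelationshipMatrix:
    """Symmetric n x n additive relationship matrix (genomic or pedigree)."""

    values: np.ndarray
    kind: str
    animal_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise DataError("relationship matrix must be square")
        if self.kind not in ("genomic", "pedigree"):
            raise DataError(f"unknown relationship kind: {self.kind!r}")
        if self.animal_ids is None:
            self.animal_ids = np.arange(n)
        else:
            self.animal_ids = np.asarray(self.animal_ids)
            if len(self.animal_ids) != n:
                raise DataError("animal_ids length does not match matrix order")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_ridge(self, ridge: float = 1e-6) -> np.ndarray:
        """Values with a small diagonal ridge; G is singular by construction
        (rows sum to zero), so downstream inversions use this."""
        return self.values + ridge * np.eye(self.n)
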