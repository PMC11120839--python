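"""Core in-memory containers shared by all pipeline stages.

Genotypes are held as a dense ``(n_samples, n_snps)`` float array of
minor-allele dosages (0/1/2, ``NaN`` for missing) together with a SNP
metadata frame and a sample index — the same layout a practitioner gets
from a PLINK binary fileset after orienting every variant to its minor
allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

#: required columns of the SNP metadata frame
SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "allele_minor", "allele_major", "maf"]


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix plus SNP and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array; entries in ``{0, 1, 2}`` or
        ``NaN`` for a missing call. Dosage counts copies of the *minor*
        allele (2 = homozygote minor, 1 = heterozygote, 0 = homozygote
        major).
    snps
        Frame with columns :data:`SNP_META_COLUMNS`; positions are 1-based.
    samples
        Individual identifiers, aligned to the rows of ``dosages``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.Index

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D samples x snps array")
        if len(self.samples) != self.dosages.shape[0]:
            raise DataError(
                f"{len(self.samples)} sample ids for {self.dosages.shape[0]} rows"
            )
        if len(self.snps) != self.dosages.shape[1]:
            raise DataError(
                f"{len(self.snps)} SNP records for {self.dosages.shape[1]} columns"
            )
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise DataError(f"snps frame lacks columns {missing}")
        if not isinstance(self.samples, pd.Index):
            self.samples = pd.Index(self.samples)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def compute_maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (minor) allele per SNP."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-SNP mean.

        Imputation happens only here, at the point of numerical work;
        the stored matrix keeps its missingness so QC stays honest.
        """
        G = self.dosages.copy()
        if np.isnan(G).any():
            col_mean = np.nanmean(G, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(G))
            G[idx] = col_mean[idx[1]]
        return G

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snps.iloc[index].reset_index(drop=True),
            self.samples,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :], self.snps.copy(), self.samples[index]
        )


@dataclass
class QcReport:
    """Bookkeeping of the marker QC cascade (MAF filter, then HWE)."""

    n_input: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_maf + self.n_removed_hwe + self.n_retained:
            raise DataError("QcReport counts do not sum to n_input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_hwe": self.n_removed_hwe,
            "n_retained": self.n_retained,
        }
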