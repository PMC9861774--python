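"""Shared genotype container.

Genotypes are held as additive minor-allele dosages: a samples x SNPs float
array with values in {0, 1, 2} and NaN for missing calls.  Variant and sample
metadata travel alongside as pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "allele1", "allele2", "minor_allele"]
SAMPLE_COLUMNS = ["id", "cohort", "sex"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive minor-allele dosage matrix.

    Attributes
    ----------
    dosage:
        ``(n_samples, n_snps)`` float array; entries are 0/1/2 counts of the
        coded (minor) allele, NaN for missing calls.
    variants:
        Per-SNP records with columns ``id, chrom, pos, allele1, allele2,
        minor_allele``; ``allele1`` is the coded allele.
    samples:
        Per-sample records with columns ``id, cohort, sex``.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D samples x SNPs array")
        n, p = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(
                f"samples table has {len(self.samples)} rows, dosage has {n}"
            )
        if len(self.variants) != p:
            raise ValueError(
                f"variants table has {len(self.variants)} rows, dosage has {p} columns"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variants table missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing column {col!r}")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids are not unique")
        if self.samples["id"].duplicated().any():
            raise ValueError("sample ids are not unique")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.variants["id"])

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["id"])

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given positional indices/masks."""
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        if sample_idx.dtype == bool:
            sample_idx = np.flatnonzero(sample_idx)
        if snp_idx.dtype == bool:
            snp_idx = np.flatnonzero(snp_idx)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(sample_idx, snp_idx)].copy(),
            variants=self.variants.iloc[snp_idx].reset_index(drop=True),
            samples=self.samples.iloc[sample_idx].reset_index(drop=True),
        )

    def dosage_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame indexed by sample id, columns = SNP ids."""
        return pd.DataFrame(
            self.dosage, index=self.sample_ids, columns=self.snp_ids
        )
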