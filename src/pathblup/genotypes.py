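"""Genotype dosage matrix container.

Dosages are coded as the count of the alternative (A1) allele, 0/1/2,
stored as float64 with ``numpy.nan`` marking missing calls.  Per-SNP
metadata (chromosome, 1-based physical position, alleles) travels with
the matrix so that pathway mapping and LD pruning can be done without
re-reading the source files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs dosage matrix with SNP metadata.

    Parameters
    ----------
    ids : list of str
        Individual identifiers, one per row of ``calls``.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``;
        ``pos`` is a 1-based physical coordinate.
    calls : numpy.ndarray
        Float array of shape (n, m); entries in {0, 1, 2} or NaN.
    """

    ids: list
    snps: pd.DataFrame
    calls: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snps)} SNPs"
            )
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps table lacks columns {missing}")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("calls must lie in {0,1,2} or be NaN")
        self.snps = self.snps.reset_index(drop=True)

    # -- basic shape -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    # -- per-SNP statistics ------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (alt) allele, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency in [0, 0.5], ignoring missing calls."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    # -- transforms ---------------------------------------------------
    def mean_impute(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-SNP mean (2p)."""
        if not np.isnan(self.calls).any():
            return self
        calls = self.calls.copy()
        p2 = 2.0 * self.allele_freq()
        nan_r, nan_c = np.where(np.isnan(calls))
        calls[nan_r, nan_c] = p2[nan_c]
        gm = replace(self, calls=calls)
        gm.meta = dict(self.meta, imputed="per-SNP mean (2p)")
        return gm

    def centered(self, snp_subset: Sequence[int] | None = None) -> np.ndarray:
        """Dosages centered by twice the allele frequency (VanRaden's M).

        Missing calls must be imputed first; NaNs raise.
        """
        idx = np.arange(self.n_snps) if snp_subset is None else np.asarray(snp_subset)
        calls = self.calls[:, idx]
        if np.isnan(calls).any():
            raise ValueError("centered() requires complete calls; mean_impute() first")
        p = calls.mean(axis=0) / 2.0
        return calls - 2.0 * p

    def subset(
        self,
        individuals: Sequence[int] | None = None,
        snps: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in rows],
            snps=self.snps.iloc[cols].reset_index(drop=True),
            calls=self.calls[np.ix_(rows, cols)],
            meta=dict(self.meta),
        )

    def sort_by_position(self) -> "GenotypeMatrix":
        order = self.snps.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return self.subset(snps=order)
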