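"""In-memory case-control cohort container.

A :class:`Cohort` bundles the three tables every downstream stage works
on: per-sample phenotypes/covariates, per-variant annotations, and the
genotype dosage matrix.  Dosages count minor alleles (0, 1, 2); missing
calls are stored as -1 and imputed only when a per-gene design matrix is
assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical exonic-function categories used throughout the package
CATEGORIES = ("synonymous", "missense", "LoF", "indel")


@dataclass
class Cohort:
    """Aligned samples x variants view of a case-control study.

    Parameters
    ----------
    samples
        One row per sample, indexed by sample id.  Must contain a
        ``status`` column coded 0 (control) / 1 (case).  May carry
        arbitrary covariate columns and a ``population`` label.
    variants
        One row per biallelic variant with columns ``chrom``, ``pos``
        (1-based), ``ref``, ``alt``, ``gene``, ``exonic_function``,
        ``cadd`` and ``af_public``.  Multi-allelic records are split
        before construction.
    genotypes
        int8 array of shape (n_samples, n_variants); -1 marks a missing
        call.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: np.ndarray
    _gene_index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n, p = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(
                f"genotype matrix has {n} rows but sample table has {len(self.samples)}"
            )
        if len(self.variants) != p:
            raise ValueError(
                f"genotype matrix has {p} columns but variant table has {len(self.variants)}"
            )
        if "status" not in self.samples.columns:
            raise ValueError("sample table must contain a 'status' column")
        status = self.samples["status"].to_numpy()
        if not np.isin(status, [0, 1]).all():
            raise ValueError("status must be coded 0 (control) / 1 (case)")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def status(self) -> np.ndarray:
        return self.samples["status"].to_numpy(dtype=np.int8)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples.index.to_numpy()

    def gene_columns(self, gene: str) -> np.ndarray:
        """Column indices of all variants annotated to ``gene``."""
        if self._gene_index is None:
            groups = pd.Series(
                np.arange(self.n_variants), index=self.variants["gene"].to_numpy()
            )
            self._gene_index = {
                g: idx.to_numpy() for g, idx in groups.groupby(level=0)
            }
        return self._gene_index.get(gene, np.empty(0, dtype=int))

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.variants["gene"]))

    # ------------------------------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotype calls."""
        return 1.0 - (self.genotypes == MISSING).mean(axis=0)

    def allele_frequency(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-variant minor-allele frequency over a sample subset.

        Missing calls are excluded from both numerator and denominator.
        """
        G = self.genotypes if mask is None else self.genotypes[mask]
        called = G != MISSING
        n_alleles = 2 * called.sum(axis=0)
        counts = np.where(called, G, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), 0.0)
        return af

    def control_allele_frequency(self, status: np.ndarray | None = None) -> np.ndarray:
        """Allele frequency in the control group (status 0)."""
        s = self.status if status is None else np.asarray(status)
        return self.allele_frequency(mask=(s == 0))

    def subset_variants(self, idx: np.ndarray) -> "Cohort":
        return Cohort(
            samples=self.samples,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
        )

    def with_status(self, status: np.ndarray) -> "Cohort":
        """Copy of the cohort with a replacement case/control assignment."""
        samples = self.samples.copy()
        samples["status"] = np.asarray(status, dtype=np.int8)
        return Cohort(samples=samples, variants=self.variants, genotypes=self.genotypes)
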