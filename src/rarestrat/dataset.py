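"""Genotype dataset container shared by the simulator, I/O and analysis layers.

A dataset is an ``n x p`` matrix of allele counts (0/1/2, ``-1`` for a
missing call) together with sample identifiers, subpopulation labels and a
per-variant annotation table (gene membership, position, private flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING = -1

REQUIRED_VARIANT_COLUMNS = ("variant_id", "gene", "private")


@dataclass
class GenotypeDataset:
    """Samples-by-variants allele-count matrix with annotations.

    Attributes
    ----------
    genotypes
        ``(n_samples, n_variants)`` integer array with entries in
        ``{0, 1, 2}`` (counted-allele dosage) or ``-1`` for missing.
    sample_ids
        Length-``n`` array of sample identifiers.
    subpop_labels
        Length-``n`` array of subpopulation labels.
    variants
        Per-variant table with at least ``variant_id``, ``gene`` and
        ``private`` (bool) columns; the simulator adds ``chrom``, ``pos``,
        ``ref``, ``alt`` and the ancestral frequency ``p0``.
    """

    genotypes: np.ndarray
    sample_ids: np.ndarray
    subpop_labels: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.sample_ids = np.asarray(self.sample_ids)
        self.subpop_labels = np.asarray(self.subpop_labels)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x variants matrix")
        n, p = self.genotypes.shape
        if len(self.sample_ids) != n or len(self.subpop_labels) != n:
            raise ValueError("sample_ids/subpop_labels length does not match genotypes")
        if len(self.variants) != p:
            raise ValueError("variant table length does not match genotype columns")
        for col in REQUIRED_VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variant table is missing required column {col!r}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def subpops(self) -> np.ndarray:
        """Sorted unique subpopulation labels."""
        return np.unique(self.subpop_labels)

    def validate(self, check_private: bool = True) -> None:
        """Check container invariants; raise ``ValueError`` on violation.

        ``check_private`` asserts that every variant flagged private has
        exactly one carrier.  Skip it on sample subsets, where a private
        carrier may have been dropped.
        """
        g = self.genotypes
        valid = (g >= MISSING) & (g <= 2)
        if not valid.all():
            raise ValueError("genotype entries must be in {-1, 0, 1, 2}")
        if len(np.unique(self.sample_ids)) != self.n_samples:
            raise ValueError("duplicate sample ids")
        if check_private:
            priv = np.flatnonzero(self.variants["private"].to_numpy())
            if priv.size:
                carriers = (g[:, priv] > 0).sum(axis=0)
                bad = np.flatnonzero(carriers != 1)
                if bad.size:
                    ids = self.variants["variant_id"].iloc[priv[bad[:5]]].tolist()
                    raise ValueError(
                        f"{bad.size} private variant(s) without exactly one carrier, e.g. {ids}"
                    )

    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        """Return a new dataset restricted to the given sample indices.

        Variant annotations (including private flags, which refer to the
        full cohort) are carried over unchanged.
        """
        index = np.asarray(index)
        return GenotypeDataset(
            genotypes=self.genotypes[index],
            sample_ids=self.sample_ids[index],
            subpop_labels=self.subpop_labels[index],
            variants=self.variants.copy(),
        )

    def gene_variant_indices(self, gene: str) -> np.ndarray:
        """Column indices of all variants annotated to ``gene``."""
        idx = np.flatnonzero(self.variants["gene"].to_numpy() == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not present in the variant table")
        return idx
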