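"""Synthetic structured exome-like cohorts.

Genotypes are simulated under the Balding-Nichols model: each variant has
an ancestral frequency ``p0`` drawn from a rare-skewed site-frequency
spectrum, and each subpopulation's frequency is drawn from
``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` where ``F`` is the per-subpopulation
divergence (Fst).  Genotypes are then independent ``Binomial(2, p_s)``
draws.  Private variants -- variants carried by exactly one sample, a
prominent feature of real exome cohorts -- are injected afterwards as
singleton heterozygotes so the single-carrier property holds by
construction.

Two presets mirror the study conditions this package targets: a
"European-like" fine structure (3 subpopulations, F = 0.005) and a
"Worldwide-like" coarse structure (4 subpopulations, F = 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset

__all__ = [
    "PopulationModel",
    "european_like",
    "worldwide_like",
    "simulate_allele_frequencies",
    "simulate_genotype_dataset",
]

# sub-stream indices spawned from the model seed; separate streams keep the
# genotype draw invariant when private_rate is toggled
_STREAM_GENES = 0
_STREAM_FREQS = 1
_STREAM_GENOTYPES = 2
_STREAM_PRIVATE = 3


@dataclass
class PopulationModel:
    """Parameters of a structured synthetic cohort.

    Parameters
    ----------
    subpop_sizes
        Number of samples per subpopulation (all >= 1).
    fst
        Balding-Nichols divergence, strictly in (0, 1).  A scalar is
        broadcast to every subpopulation.
    n_genes, variants_per_gene
        Number of genes and the Poisson mean of (non-private) variants per
        gene (at least one variant per gene).  The default 18.7 matches the
        biallelic-SNP-to-gene ratio of a large real exome cohort
        (~329k SNPs over ~17.6k genes).
    sfs_shape
        ``(a, b)`` of the Beta distribution of the ancestral frequency,
        truncated to ``(0, sfs_max]``.  The default Beta(0.2, 2) gives a
        heavily rare-skewed spectrum.
    private_rate
        Expected number of injected private variants per sample.  ``None``
        targets a private:non-private ratio of about 1:3.
    """

    subpop_sizes: Sequence[int] = (200, 200, 200)
    fst: float | Sequence[float] = 0.005
    n_genes: int = 200
    variants_per_gene: float = 18.7
    sfs_shape: tuple[float, float] = (0.2, 2.0)
    sfs_max: float = 0.5
    private_rate: float | None = None
    seed: int = 0
    subpop_names: Sequence[str] | None = None
    fst_per_subpop: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.subpop_sizes = tuple(int(s) for s in self.subpop_sizes)
        if len(self.subpop_sizes) < 1 or any(s < 1 for s in self.subpop_sizes):
            raise ValueError("subpop_sizes must be >= 1")
        fst = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_subpops,)).copy()
        if np.any(fst <= 0.0) or np.any(fst >= 1.0):
            raise ValueError("fst must be strictly in (0, 1)")
        self.fst_per_subpop = fst
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.variants_per_gene <= 0:
            raise ValueError("variants_per_gene must be positive")
        if not (0.0 < self.sfs_max <= 1.0):
            raise ValueError("sfs_max must be in (0, 1]")
        if self.private_rate is not None and self.private_rate < 0:
            raise ValueError("private_rate must be >= 0")
        if self.subpop_names is None:
            self.subpop_names = tuple(f"pop{i + 1}" for i in range(self.n_subpops))
        elif len(self.subpop_names) != self.n_subpops:
            raise ValueError("subpop_names length must match subpop_sizes")

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_sizes)

    @property
    def n_samples(self) -> int:
        return int(sum(self.subpop_sizes))

    def resolved_private_rate(self) -> float:
        """Private variants per sample; default targets private:other = 1:3."""
        if self.private_rate is not None:
            return float(self.private_rate)
        expected_variants = self.n_genes * self.variants_per_gene
        return expected_variants / 3.0 / self.n_samples

    def _rngs(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return [np.random.default_rng(c) for c in children]


def european_like(
    n_per_subpop: int = 200, n_genes: int = 200, seed: int = 0, **kwargs
) -> PopulationModel:
    """Fine-scale (within-continent) structure: 3 subpopulations, F = 0.005."""
    kwargs.setdefault("subpop_names", ("north", "middle", "south"))
    return PopulationModel(
        subpop_sizes=(n_per_subpop,) * 3, fst=0.005, n_genes=n_genes, seed=seed, **kwargs
    )


def worldwide_like(
    n_per_subpop: int = 200, n_genes: int = 200, seed: int = 0, **kwargs
) -> PopulationModel:
    """Coarse (between-continent) structure: 4 subpopulations, F = 0.1."""
    kwargs.setdefault("subpop_names", ("europe", "mideast", "nafrica", "sasia"))
    return PopulationModel(
        subpop_sizes=(n_per_subpop,) * 4, fst=0.1, n_genes=n_genes, seed=seed, **kwargs
    )


def _gene_sizes(model: PopulationModel, rng: np.random.Generator) -> np.ndarray:
    """Poisson(variants_per_gene) counts, floored at one variant per gene."""
    sizes = rng.poisson(model.variants_per_gene, size=model.n_genes)
    return np.maximum(sizes, 1)


def _draw_p0(model: PopulationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral frequencies from the truncated-Beta spectrum, in (0, sfs_max]."""
    a, b = model.sfs_shape
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(a, b, size=max(n - filled, 16))
        draw = draw[(draw > 0.0) & (draw <= model.sfs_max)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_allele_frequencies(
    model: PopulationModel,
    n_variants: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw ancestral and per-subpopulation allele frequencies.

    Returns a frame with one row per variant: ``p0`` plus one frequency
    column per subpopulation.  Variants that come out monomorphic by
    construction (all subpopulation frequencies 0, or all 1) are resampled
    so every emitted variant can segregate.
    """
    if rng is None:
        rng = model._rngs()[_STREAM_FREQS]
    if n_variants is None:
        n_variants = int(_gene_sizes(model, model._rngs()[_STREAM_GENES]).sum())

    k = model.n_subpops
    fst = model.fst_per_subpop
    p0 = np.empty(n_variants)
    freqs = np.empty((n_variants, k))
    todo = np.arange(n_variants)
    while todo.size:
        new_p0 = _draw_p0(model, todo.size, rng)
        alpha = new_p0[:, None] * (1.0 - fst) / fst
        beta = (1.0 - new_p0)[:, None] * (1.0 - fst) / fst
        new_freqs = rng.beta(alpha, beta)
        p0[todo] = new_p0
        freqs[todo] = new_freqs
        degenerate = (new_freqs.max(axis=1) <= 0.0) | (new_freqs.min(axis=1) >= 1.0)
        todo = todo[degenerate]

    table = pd.DataFrame({"p0": p0})
    for s, name in enumerate(model.subpop_names):
        table[f"freq_{name}"] = freqs[:, s]
    return table


def simulate_genotype_dataset(model: PopulationModel) -> GenotypeDataset:
    """Simulate a complete exome-like cohort from ``model``.

    Non-private genotypes are ``Binomial(2, p_s)`` draws given the
    subpopulation frequency; private variants are injected as singleton
    heterozygotes at ``private_rate`` per sample and flagged.  Variants are
    ordered by gene, with positions spaced 100 bp apart.
    """
    rng_genes, rng_freqs, rng_geno, rng_priv = model._rngs()

    gene_sizes = _gene_sizes(model, rng_genes)
    gene_names = np.array([f"gene{g + 1:05d}" for g in range(model.n_genes)])
    gene_of_variant = np.repeat(np.arange(model.n_genes), gene_sizes)
    p = int(gene_sizes.sum())

    freq_table = simulate_allele_frequencies(model, n_variants=p, rng=rng_freqs)
    freqs = freq_table.iloc[:, 1:].to_numpy()

    n = model.n_samples
    genotypes = np.empty((n, p), dtype=np.int8)
    labels = np.empty(n, dtype=object)
    row = 0
    for s, size in enumerate(model.subpop_sizes):
        genotypes[row : row + size] = rng_geno.binomial(
            2, freqs[:, s], size=(size, p)
        ).astype(np.int8)
        labels[row : row + size] = model.subpop_names[s]
        row += size

    # private variants: one singleton heterozygote each
    rate = model.resolved_private_rate()
    per_sample = rng_priv.poisson(rate, size=n) if rate > 0 else np.zeros(n, dtype=int)
    n_priv = int(per_sample.sum())
    carrier_of_private = np.repeat(np.arange(n), per_sample)
    gene_of_private = rng_priv.integers(0, model.n_genes, size=n_priv)

    priv_geno = np.zeros((n, n_priv), dtype=np.int8)
    priv_geno[carrier_of_private, np.arange(n_priv)] = 1

    all_geno = np.concatenate([genotypes, priv_geno], axis=1)
    all_gene = np.concatenate([gene_of_variant, gene_of_private])
    all_p0 = np.concatenate([freq_table["p0"].to_numpy(), np.full(n_priv, np.nan)])
    all_priv = np.concatenate([np.zeros(p, bool), np.ones(n_priv, bool)])

    order = np.lexsort((np.arange(p + n_priv), all_priv, all_gene))
    all_geno = all_geno[:, order]

    variants = pd.DataFrame(
        {
            "variant_id": [f"var{i + 1:07d}" for i in range(p + n_priv)],
            "chrom": "1",
            "pos": (np.arange(p + n_priv) + 1) * 100,
            "ref": "A",
            "alt": "G",
            "gene": gene_names[all_gene[order]],
            "p0": all_p0[order],
            "private": all_priv[order],
        }
    )
    sample_ids = np.array([f"S{i + 1:05d}" for i in range(n)])
    return GenotypeDataset(
        genotypes=all_geno,
        sample_ids=sample_ids,
        subpop_labels=labels.astype(str),
        variants=variants,
    )
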