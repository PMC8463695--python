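"""Genetic-similarity machinery: MAF classes, normalization, LD pruning,
similarity matrices, PCA, genetic distances and neighborhoods.

The similarity matrix for a variant set ``H`` is ``S = X~ X~'`` where
``X~`` is the genotype matrix normalized per column to
``(x - mu) / sqrt(f (1 - f))``, ``f`` being the observed (unfolded)
frequency of the counted allele.  Principal components are the
eigenvectors of ``S`` scaled so component ``k`` has squared norm equal to
its eigenvalue, and the genetic distance between samples is the
eigenvalue-weighted squared Euclidean distance over the top ``K`` (default
10) components -- the same distance that defines local-permutation
neighborhoods and reference-based cohort selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, GenotypeDataset

__all__ = [
    "VariantSet",
    "NormalizedGenotypes",
    "SimilarityMatrix",
    "PCModel",
    "NeighborGraph",
    "compute_maf",
    "classify_variants",
    "normalize_genotypes",
    "ld_prune",
    "similarity_matrix",
    "pca",
    "genetic_distance",
    "nearest_neighbors",
    "select_by_reference_distance",
    "write_scores_tsv",
    "write_similarity_tsv",
]

#: MAF class bounds: rare (RV), low-frequency (LFV), common (CV) variants
MAF_CLASS_BOUNDS = {"RV": (0.0, 0.01), "LFV": (0.01, 0.05), "CV": (0.05, 0.5)}


@dataclass
class VariantSet:
    """A MAF-defined set of (non-private, polymorphic) variant indices."""

    category: str
    indices: np.ndarray
    maf_bounds: tuple[float, float]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class NormalizedGenotypes:
    """Column-centered, frequency-scaled genotypes for a variant set."""

    matrix: np.ndarray
    mu: np.ndarray
    freq: np.ndarray
    variant_indices: np.ndarray
    category: str = "ALLV"
    sample_ids: np.ndarray | None = None


@dataclass
class SimilarityMatrix:
    """``n x n`` genetic similarity ``S = X~ X~'`` for a variant set."""

    matrix: np.ndarray
    category: str = "ALLV"
    n_variants: int = 0
    sample_ids: np.ndarray | None = None


@dataclass
class PCModel:
    """Principal-component scores and eigenvalues of a similarity matrix.

    ``scores[:, k]`` has squared norm ``eigenvalues[k]`` (eigenvector times
    the square root of its eigenvalue); eigenvalues are non-increasing.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    category: str = "ALLV"
    sample_ids: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class NeighborGraph:
    """Per-sample ordered nearest neighbors under the genetic distance."""

    neighbors: np.ndarray  # (n, min(N, n-1)) sample indices
    distances: np.ndarray = field(repr=False, default=None)
    n_requested: int = 0

    @property
    def n_samples(self) -> int:
        return self.neighbors.shape[0]

    @property
    def n_neighbors(self) -> int:
        return self.neighbors.shape[1]


def _as_genotype_matrix(data) -> np.ndarray:
    if isinstance(data, GenotypeDataset):
        return data.genotypes
    return np.asarray(data)


def compute_maf(dataset) -> np.ndarray:
    """Folded minor-allele frequency per variant, in ``[0, 0.5]``.

    Computed on non-missing genotypes; a variant with every call missing
    gets ``nan``.
    """
    g = _as_genotype_matrix(dataset)
    if g.shape[0] < 1:
        raise ValueError("need at least one sample")
    observed = g != MISSING
    counts = np.where(observed, g, 0).sum(axis=0, dtype=np.int64)
    denom = 2 * observed.sum(axis=0, dtype=np.int64)
    # fold on integer allele counts so boundary MAFs (e.g. exactly 0.05)
    # are not perturbed by floating-point subtraction
    minor = np.minimum(counts, denom - counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, minor / np.maximum(denom, 1), np.nan)


def unfolded_freq(dataset) -> np.ndarray:
    """Observed frequency of the counted (ALT) allele, unfolded."""
    g = _as_genotype_matrix(dataset)
    observed = g != MISSING
    counts = np.where(observed, g, 0).sum(axis=0, dtype=np.int64)
    denom = 2 * observed.sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)


def classify_variants(mafs: np.ndarray, private_flags: np.ndarray) -> dict[str, VariantSet]:
    """Partition variants into RV / LFV / CV sets plus their union ALLV.

    Bounds (on the total-sample folded MAF): RV ``0 < MAF < 0.01``,
    LFV ``0.01 <= MAF < 0.05``, CV ``MAF >= 0.05``.  Private and
    monomorphic (MAF 0 or undefined) variants belong to no set.
    """
    mafs = np.asarray(mafs, dtype=float)
    private_flags = np.asarray(private_flags, dtype=bool)
    if mafs.shape != private_flags.shape:
        raise ValueError("mafs and private_flags must be aligned")
    eligible = (~private_flags) & np.isfinite(mafs) & (mafs > 0.0)
    sets = {}
    rv = eligible & (mafs < 0.01)
    lfv = eligible & (mafs >= 0.01) & (mafs < 0.05)
    cv = eligible & (mafs >= 0.05)
    for name, mask in (("RV", rv), ("LFV", lfv), ("CV", cv)):
        sets[name] = VariantSet(name, np.flatnonzero(mask), MAF_CLASS_BOUNDS[name])
    sets["ALLV"] = VariantSet("ALLV", np.flatnonzero(eligible), (0.0, 0.5))
    return sets


def _resolve_indices(variant_set) -> tuple[np.ndarray, str]:
    if isinstance(variant_set, VariantSet):
        return np.asarray(variant_set.indices), variant_set.category
    return np.asarray(variant_set), "ALLV"


def normalize_genotypes(dataset, variant_set) -> NormalizedGenotypes:
    """Center and scale genotype columns: ``(x - mu) / sqrt(f (1 - f))``.

    ``f`` is the unfolded observed allele frequency.  Missing calls are
    mean-imputed (hence contribute zero after centering).  Monomorphic
    columns (``f`` of 0 or 1) raise, since the scale is undefined.
    """
    idx, category = _resolve_indices(variant_set)
    g = _as_genotype_matrix(dataset)[:, idx].astype(float)
    missing = g == MISSING
    g[missing] = np.nan
    mu = np.nanmean(g, axis=0)
    f = mu / 2.0
    bad = ~((f > 0.0) & (f < 1.0))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} monomorphic (or all-missing) column(s) in the variant set; "
            "normalization denominator would be zero"
        )
    g = np.where(missing, mu, g)
    matrix = (g - mu) / np.sqrt(f * (1.0 - f))
    ids = dataset.sample_ids if isinstance(dataset, GenotypeDataset) else None
    return NormalizedGenotypes(matrix, mu, f, idx, category, ids)


def _r2_matrix(g: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation between genotype columns."""
    x = g - g.mean(axis=0)
    sd = np.sqrt((x**2).sum(axis=0))
    sd[sd == 0] = np.nan
    c = (x.T @ x) / np.outer(sd, sd)
    r2 = np.nan_to_num(c**2)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    dataset,
    variant_set,
    r2_threshold: float = 0.2,
    window: int = 50,
    step: int = 5,
    mafs: np.ndarray | None = None,
) -> VariantSet:
    """Greedy windowed LD pruning at squared-correlation > ``r2_threshold``.

    Within each window, while any retained pair exceeds the threshold the
    member with the lower MAF is dropped (ties: the later variant).
    ``window=None`` or a window covering the whole set gives global
    pruning.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    idx, category = _resolve_indices(variant_set)
    if idx.size <= 1:
        return VariantSet(category, idx.copy(), getattr(variant_set, "maf_bounds", (0.0, 0.5)))
    g_all = _as_genotype_matrix(dataset)
    if mafs is None:
        mafs = compute_maf(g_all)
    keep = np.ones(idx.size, dtype=bool)
    m = idx.size
    if window is None or window >= m:
        starts = [0]
        window = m
    else:
        starts = list(range(0, max(m - window, 0) + 1, step))
        if starts[-1] + window < m:
            starts.append(m - window)
    for s in starts:
        local = np.arange(s, min(s + window, m))
        local = local[keep[local]]
        if local.size <= 1:
            continue
        sub = g_all[:, idx[local]].astype(float)
        sub[sub == MISSING] = np.nan
        col_mean = np.nanmean(sub, axis=0)
        sub = np.where(np.isnan(sub), col_mean, sub)
        r2 = _r2_matrix(sub)
        active = np.ones(local.size, dtype=bool)
        while True:
            r2a = np.where(np.outer(active, active), r2, 0.0)
            i, j = np.unravel_index(np.argmax(r2a), r2a.shape)
            if r2a[i, j] <= r2_threshold:
                break
            vi, vj = idx[local[i]], idx[local[j]]
            # drop the lower-MAF member; on a tie, the later variant index
            if mafs[vi] < mafs[vj] or (mafs[vi] == mafs[vj] and vi > vj):
                drop = i
            else:
                drop = j
            active[drop] = False
            keep[local[drop]] = False
    return VariantSet(category, idx[keep], getattr(variant_set, "maf_bounds", (0.0, 0.5)))


def similarity_matrix(norm: NormalizedGenotypes) -> SimilarityMatrix:
    """``S = X~ X~'`` over the normalized variant set."""
    if norm.matrix.shape[1] < 1:
        raise ValueError("need at least one variant")
    s = norm.matrix @ norm.matrix.T
    s = (s + s.T) / 2.0
    return SimilarityMatrix(s, norm.category, norm.matrix.shape[1], norm.sample_ids)


def pca(sim: SimilarityMatrix, n_components: int = 10) -> PCModel:
    """Eigendecomposition of the similarity matrix.

    Scores are eigenvectors scaled by the square root of their eigenvalue
    (component ``k`` has squared norm ``lambda_k``); eigenvalues are
    returned non-increasing with tiny negatives clipped to zero.  The sign
    convention makes each component's largest-magnitude loading positive.
    """
    s = sim.matrix
    n = s.shape[0]
    if not np.all(np.isfinite(s)):
        raise ValueError("similarity matrix has non-finite entries")
    if n_components > n - 1:
        raise ValueError(f"n_components={n_components} exceeds n-1={n - 1}")
    vals, vecs = np.linalg.eigh(s)
    order = np.argsort(vals, kind="stable")[::-1][:n_components]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    for k in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = vecs * np.sqrt(vals)
    return PCModel(scores, vals, sim.category, sim.sample_ids)


def genetic_distance(pc: PCModel, K: int = 10) -> np.ndarray:
    """Pairwise squared genetic distance over the top ``K`` components.

    ``d_ij^2 = sum_k lambda_k (PC_ki - PC_kj)^2`` -- an eigenvalue-weighted
    squared Euclidean distance in score space.  Symmetric, zero diagonal.
    """
    if K > pc.n_components:
        raise ValueError(f"K={K} exceeds available components ({pc.n_components})")
    w = pc.scores[:, :K] * np.sqrt(pc.eigenvalues[:K])
    sq = (w**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (w @ w.T)
    d2 = np.maximum(d2, 0.0)
    d2 = (d2 + d2.T) / 2.0
    np.fill_diagonal(d2, 0.0)
    return d2


def nearest_neighbors(distances: np.ndarray, N: int = 30) -> NeighborGraph:
    """Per sample, the ``N`` nearest other samples (ties broken by index)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    take = min(N, n - 1)
    nbr = np.empty((n, take), dtype=np.int64)
    nbr_d = np.empty((n, take))
    order_idx = np.arange(n)
    # argpartition pre-selects candidates; ties at the cut boundary are
    # resolved by pulling in every index at the boundary distance before
    # the index-stable sort, preserving the lowest-index-first tie rule
    k_part = min(take + 1, n - 1)
    for i in range(n):
        row = d[i]
        cand = np.argpartition(row, k_part)[: k_part + 1]
        boundary = row[cand].max()
        cand = np.flatnonzero(row <= boundary)
        order = cand[np.lexsort((order_idx[cand], row[cand]))]
        order = order[order != i][:take]
        nbr[i] = order
        nbr_d[i] = row[order]
    return NeighborGraph(nbr, nbr_d, N)


def select_by_reference_distance(
    pc: PCModel, reference: int | str, threshold: float, K: int = 10
) -> np.ndarray:
    """Samples whose squared genetic distance to ``reference`` is below
    ``threshold`` (the reference itself, at distance zero, is included).

    ``reference`` may be a sample index, or a sample id when the PC model
    carries ids.  Returns the selected indices (or ids when available).
    """
    if isinstance(reference, str):
        if pc.sample_ids is None:
            raise ValueError("PC model has no sample ids; pass an integer index")
        hits = np.flatnonzero(np.asarray(pc.sample_ids) == reference)
        if hits.size != 1:
            raise ValueError(f"reference sample {reference!r} not found")
        ref = int(hits[0])
    else:
        ref = int(reference)
    if K > pc.n_components:
        raise ValueError(f"K={K} exceeds available components ({pc.n_components})")
    w = pc.scores[:, :K] * np.sqrt(pc.eigenvalues[:K])
    d2 = ((w - w[ref]) ** 2).sum(axis=1)
    selected = np.flatnonzero(d2 < threshold)
    if pc.sample_ids is not None:
        return np.asarray(pc.sample_ids)[selected]
    return selected


def _ids_or_range(sample_ids, n: int) -> np.ndarray:
    if sample_ids is None:
        return np.array([f"sample{i}" for i in range(n)])
    return np.asarray(sample_ids)


def write_scores_tsv(pc: PCModel, path: str) -> None:
    """Write PC scores as a tab-delimited table (sample_id + PC columns)."""
    import pandas as pd

    n = pc.scores.shape[0]
    table = pd.DataFrame(
        pc.scores, columns=[f"PC{k + 1}" for k in range(pc.n_components)]
    )
    table.insert(0, "sample_id", _ids_or_range(pc.sample_ids, n))
    table.to_csv(path, sep="\t", index=False)


def write_similarity_tsv(sim: SimilarityMatrix, path: str) -> None:
    """Write a similarity matrix as a tab-delimited table (sample_id + columns)."""
    import pandas as pd

    n = sim.matrix.shape[0]
    ids = _ids_or_range(sim.sample_ids, n)
    table = pd.DataFrame(sim.matrix, columns=ids)
    table.insert(0, "sample_id", ids)
    table.to_csv(path, sep="\t", index=False)
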