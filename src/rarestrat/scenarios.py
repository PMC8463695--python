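"""Simulation-study engine: stratified case/control designs, penetrance-based
phenotypes, and type-I-error / power evaluation.

Null phenotypes are assigned independently of genotype given the
subpopulation labels: a fixed overall case fraction (15% by default) is
allocated across subpopulations by scenario weights -- proportional
("NoPS"), skewed ("ModeratePS") or concentrated on a single subpopulation
("HighPS") -- and cases are drawn uniformly without replacement within
each subpopulation.

Alternative phenotypes follow a gene-level penetrance model: carrier
status is the indicator of at least one *causal* rare variant of the gene
(no dose effect; the relative risk is defined at the gene level), and per
subgroup ``s`` the carrier and non-carrier penetrances solve

    f_noncarrier = K_s / (p_s RR + 1 - p_s),    f_carrier = RR f_noncarrier,

where ``p_s`` is the observed carrier frequency and ``K_s`` the subgroup
disease frequency implied by the scenario's case allocation.

Type-I error is summarized as ``fp = #{p <= alpha} / G`` with an adjusted
prediction interval ``alpha +/- Z_{0.975/#methods} sqrt(alpha(1-alpha)/G)``
accounting for the number of methods compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np
import pandas as pd
from scipy import stats

from .burden import (
    cast_lrt_from_counts,
    gene_filter,
    logistic_lrt,
    pc_adjusted_test,
    select_gene_variants,
    wss_score,
    _logit_fit,
    _intercept_only_ll,
)
from .dataset import GenotypeDataset
from .lmm import SimilarityEigen, _fit_rotated
from .locperm import (
    DEFAULT_SWEEPS,
    PermutationSet,
    locperm_scan,
    sample_local_permutations,
)
from .structure import (
    NeighborGraph,
    PCModel,
    classify_variants,
    compute_maf,
    genetic_distance,
    ld_prune,
    nearest_neighbors,
    normalize_genotypes,
    pca,
    similarity_matrix,
)

__all__ = [
    "ScenarioSpec",
    "no_ps",
    "moderate_ps",
    "high_ps",
    "assign_null_phenotypes",
    "SmallSampleDesign",
    "build_small_sample_design",
    "PenetranceEntry",
    "compute_penetrance",
    "PowerGene",
    "select_power_genes",
    "simulate_alt_phenotypes",
    "EvalResult",
    "evaluate_type1",
    "PowerEstimate",
    "evaluate_power",
    "Pretreatment",
    "pretreat",
    "BenchmarkResult",
    "run_benchmark",
    "run_power",
    "run_small_sample_power",
]

DEFAULT_CASE_FRACTION = 0.15
#: moderate-stratification case allocation over subpopulations
MODERATE_WEIGHTS = {3: (0.7, 0.2, 0.1), 4: (0.7, 0.15, 0.1, 0.05)}


# ---------------------------------------------------------------------------
# scenario specification and null phenotypes


@dataclass
class ScenarioSpec:
    """A stratification scenario: how cases are spread over subpopulations.

    ``allocation`` gives per-subpopulation case-allocation weights aligned
    with the sorted unique labels; ``None`` means proportional to
    subpopulation size (no stratification).
    """

    name: str
    case_fraction: float = DEFAULT_CASE_FRACTION
    allocation: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")
        if self.allocation is not None:
            w = np.asarray(self.allocation, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("allocation weights must be >= 0 and sum to 1")
            self.allocation = tuple(w)


def no_ps(case_fraction: float = DEFAULT_CASE_FRACTION) -> ScenarioSpec:
    """No stratification: cases proportional to subpopulation size."""
    return ScenarioSpec("NoPS", case_fraction, None)


def moderate_ps(n_subpops: int, case_fraction: float = DEFAULT_CASE_FRACTION) -> ScenarioSpec:
    """Moderate stratification: cases mostly from some subpopulations."""
    if n_subpops not in MODERATE_WEIGHTS:
        raise ValueError("moderate_ps presets exist for 3 or 4 subpopulations")
    return ScenarioSpec("ModeratePS", case_fraction, MODERATE_WEIGHTS[n_subpops])


def high_ps(n_subpops: int, case_fraction: float = DEFAULT_CASE_FRACTION) -> ScenarioSpec:
    """High stratification: every case from the first subpopulation."""
    weights = (1.0,) + (0.0,) * (n_subpops - 1)
    return ScenarioSpec("HighPS", case_fraction, weights)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by ``weights`` (largest remainder)."""
    raw = total * weights
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def case_targets(labels: np.ndarray, spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(subpops, subpop sizes, per-subpop case counts) for a scenario."""
    labels = np.asarray(labels)
    subpops, sizes = np.unique(labels, return_counts=True)
    n_cases = int(round(spec.case_fraction * labels.size))
    if spec.allocation is None:
        weights = sizes / labels.size
    else:
        if len(spec.allocation) != subpops.size:
            raise ValueError(
                f"scenario {spec.name}: {len(spec.allocation)} weights for {subpops.size} subpopulations"
            )
        weights = np.asarray(spec.allocation)
    targets = _largest_remainder(n_cases, weights)
    short = targets - sizes
    if np.any(short > 0):
        bad = ", ".join(
            f"{subpops[i]} (need {targets[i]}, have {sizes[i]})"
            for i in np.flatnonzero(short > 0)
        )
        raise ValueError(f"scenario {spec.name}: case allocation infeasible for {bad}")
    return subpops, sizes, targets


def assign_null_phenotypes(
    labels: np.ndarray, spec: ScenarioSpec, replicate_seed: int
) -> np.ndarray:
    """Phenotypes independent of genotype given subpopulation labels.

    Within each subpopulation the scenario's case count is drawn uniformly
    without replacement.
    """
    labels = np.asarray(labels)
    subpops, _, targets = case_targets(labels, spec)
    rng = np.random.default_rng(replicate_seed)
    y = np.zeros(labels.size, dtype=np.int8)
    for sp, t in zip(subpops, targets):
        if t == 0:
            continue
        pool = np.flatnonzero(labels == sp)
        y[rng.choice(pool, size=t, replace=False)] = 1
    return y


# ---------------------------------------------------------------------------
# small-sample designs


@dataclass
class SmallSampleDesign:
    """A few-cases design: e.g. 50 cases from one subpopulation plus a
    control panel that is matched (same subpopulation) or drawn from the
    whole cohort.

    ``case_pool`` / ``control_pool`` are subpopulation labels, or ``None``
    for the whole sample.
    """

    n_cases: int = 50
    case_pool: str | None = None
    n_controls: int = 100
    control_pool: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            cp = self.case_pool or "W"
            kp = self.control_pool or "W"
            self.name = f"{self.n_cases}{cp}-{self.n_controls}{kp}"


def _pool_indices(labels: np.ndarray, pool: str | None) -> np.ndarray:
    if pool is None:
        return np.arange(labels.size)
    idx = np.flatnonzero(labels == pool)
    if idx.size == 0:
        raise ValueError(f"subpopulation {pool!r} not present")
    return idx


def build_small_sample_design(
    labels: np.ndarray, design: SmallSampleDesign, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a small-sample case/control subset under the null.

    Cases and controls are drawn without replacement and are disjoint.
    Returns (sample indices, phenotype vector aligned to them).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    case_pool = _pool_indices(labels, design.case_pool)
    if case_pool.size < design.n_cases:
        raise ValueError(
            f"design {design.name}: {design.n_cases} cases requested, pool has {case_pool.size}"
        )
    cases = rng.choice(case_pool, size=design.n_cases, replace=False)
    control_pool = np.setdiff1d(_pool_indices(labels, design.control_pool), cases)
    if control_pool.size < design.n_controls:
        raise ValueError(
            f"design {design.name}: {design.n_controls} controls requested, "
            f"pool has {control_pool.size} after removing cases"
        )
    controls = rng.choice(control_pool, size=design.n_controls, replace=False)
    subset = np.concatenate([cases, controls])
    y = np.concatenate(
        [np.ones(design.n_cases, dtype=np.int8), np.zeros(design.n_controls, dtype=np.int8)]
    )
    return subset, y


# ---------------------------------------------------------------------------
# penetrance model


@dataclass
class PenetranceEntry:
    """Carrier / non-carrier penetrance for one subgroup."""

    p_carrier_freq: float
    k_disease_freq: float
    rr: float
    f_carrier: float
    f_noncarrier: float


def compute_penetrance(p_s: float, k_s: float, rr: float) -> PenetranceEntry:
    """Solve the penetrances from carrier frequency, disease frequency, RR.

    ``f_noncarrier = K / (p RR + 1 - p)`` and ``f_carrier = RR f_noncarrier``
    satisfy the mixture identity ``p f_c + (1-p) f_n = K`` exactly.  A
    combination pushing ``f_carrier`` above 1 is infeasible and raises.
    """
    if not (0.0 < p_s < 1.0):
        raise ValueError("carrier frequency p_s must be in (0, 1)")
    if not (0.0 < k_s < 1.0):
        raise ValueError("disease frequency K_s must be in (0, 1)")
    if rr < 1.0:
        raise ValueError("relative risk must be >= 1")
    f_non = k_s / (p_s * rr + 1.0 - p_s)
    f_car = rr * f_non
    if f_car > 1.0 or f_non > 1.0:
        raise ValueError(
            f"infeasible penetrance: f_carrier={f_car:.4g} exceeds 1 for p={p_s}, K={k_s}, RR={rr}"
        )
    return PenetranceEntry(p_s, k_s, rr, f_car, f_non)


@dataclass
class PowerGene:
    """A gene selected for power studies, with its designated causal variants."""

    gene: str
    variant_indices: np.ndarray
    causal_indices: np.ndarray
    causal_carrier: np.ndarray = field(repr=False, default=None)  # (n,) bool
    cum_freq: float = 0.0
    carrier_count: int = 0


def select_power_genes(
    dataset: GenotypeDataset,
    n_genes: int = 10,
    target_cum_freq: float = 0.10,
    causal_fraction: float = 0.5,
    seed: int = 0,
    maf_threshold: float = 0.05,
    min_carriers: int = 10,
    mafs: np.ndarray | None = None,
    case_subpop: str | None = None,
    min_case_pool_carrier_freq: float = 0.0,
) -> list[PowerGene]:
    """Pick genes whose cumulative rare-variant frequency is nearest the
    target (~20% carriers at 10%), then mark ~``causal_fraction`` of each
    gene's rare variants causal (same direction of effect; round half up).

    For few-cases designs whose cases come from one subpopulation, the
    design-implied disease frequency there can be high (e.g. 50 cases out
    of 150 analyzed), and the penetrance model is only solvable when the
    causal-carrier frequency in that subpopulation is at least
    ``(RR K - 1) / (RR - 1)``.  ``case_subpop`` plus
    ``min_case_pool_carrier_freq`` filter the candidates accordingly.
    """
    if mafs is None:
        mafs = compute_maf(dataset)
    rng = np.random.default_rng(seed)
    pool_mask = None
    if case_subpop is not None:
        pool_mask = np.asarray(dataset.subpop_labels) == case_subpop
        if not pool_mask.any():
            raise ValueError(f"subpopulation {case_subpop!r} not present")
    candidates = []
    for gene in dataset.variants["gene"].unique():
        sel = select_gene_variants(dataset, gene, maf_threshold, mafs)
        if sel.carrier_count < min_carriers or len(sel.variant_indices) == 0:
            continue
        cum = float(np.sum(sel.mafs))
        candidates.append((abs(cum - target_cum_freq), gene, sel, cum))
    candidates.sort(key=lambda t: (t[0], t[1]))
    out = []
    for _, gene, sel, cum in candidates:
        if len(out) == n_genes:
            break
        m = len(sel.variant_indices)
        n_causal = int(np.floor(m * causal_fraction + 0.5))  # round half up
        if causal_fraction > 0:
            n_causal = max(n_causal, 1)
        n_causal = min(n_causal, m)
        causal_local = np.sort(rng.choice(m, size=n_causal, replace=False))
        carrier = sel.minor_dosage[:, causal_local].sum(axis=1) > 0
        if pool_mask is not None:
            if float(carrier[pool_mask].mean()) < min_case_pool_carrier_freq:
                continue
        out.append(
            PowerGene(
                gene=gene,
                variant_indices=sel.variant_indices,
                causal_indices=sel.variant_indices[causal_local],
                causal_carrier=carrier,
                cum_freq=cum,
                carrier_count=sel.carrier_count,
            )
        )
    if len(out) < n_genes:
        raise ValueError(
            f"only {len(out)} genes eligible for power selection (need {n_genes})"
        )
    return out


def _phenotypes_from_penetrance(
    labels: np.ndarray,
    carrier: np.ndarray,
    k_by_subpop: dict[str, float],
    rr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli phenotypes from subgroup-specific penetrances."""
    labels = np.asarray(labels)
    carrier = np.asarray(carrier, dtype=bool)
    prob = np.zeros(labels.size)
    for sp, k_s in k_by_subpop.items():
        mask = labels == sp
        if not mask.any():
            continue
        if k_s <= 0.0:
            continue  # no disease in this subgroup under the scenario
        p_s = float(carrier[mask].mean())
        if p_s <= 0.0 or p_s >= 1.0:
            # no (or only) carriers in the subgroup: everyone shares the
            # subgroup disease frequency
            prob[mask] = k_s
            continue
        pen = compute_penetrance(p_s, k_s, rr)
        prob[mask] = np.where(carrier[mask], pen.f_carrier, pen.f_noncarrier)
    return (rng.random(labels.size) < prob).astype(np.int8)


def simulate_alt_phenotypes(
    labels: np.ndarray,
    carrier: np.ndarray,
    spec: ScenarioSpec,
    rr: float,
    replicate_seed,
) -> np.ndarray:
    """Phenotypes under H1 for one gene.

    ``carrier`` is the indicator of >= 1 causal variant.  The subgroup
    disease frequency ``K_s`` is the scenario's case allocation divided by
    the subgroup size, so the expected overall case fraction and its
    distribution over subpopulations match the null design of the same
    scenario.
    """
    labels = np.asarray(labels)
    subpops, sizes, targets = case_targets(labels, spec)
    k_by_subpop = {sp: t / s for sp, s, t in zip(subpops, sizes, targets)}
    rng = np.random.default_rng(replicate_seed)
    return _phenotypes_from_penetrance(labels, carrier, k_by_subpop, rr, rng)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalResult:
    """Type-I-error summary with the methods-adjusted prediction interval."""

    method: str
    alpha: float
    fp: float
    G: int
    pi_lower: float
    pi_upper: float
    verdict: str
    n_excluded: int = 0


def evaluate_type1(
    p_values: np.ndarray,
    alpha: float,
    n_methods: int = 1,
    method: str = "",
    center: str = "nominal",
) -> EvalResult:
    """False-positive rate with the adjusted prediction interval.

    ``fp = #{p <= alpha} / G``; the interval is
    ``center +/- Z_{0.975/#methods} sqrt(b (1 - b) / G)`` where the normal
    quantile is taken at ``1 - 0.025 / n_methods``.  ``center="nominal"``
    (default) centers at ``alpha`` -- the fixed per-table interval used to
    flag methods; ``center="observed"`` centers at the observed ``fp``.
    Missing p-values are excluded from ``G`` and counted.
    """
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    n_excluded = int((~ok).sum())
    p = p[ok]
    g = p.size
    if g < 1:
        raise ValueError("need at least one p-value")
    fp = float((p <= alpha).mean())
    z = stats.norm.ppf(1.0 - 0.025 / n_methods)
    base = alpha if center == "nominal" else fp
    half = z * np.sqrt(base * (1.0 - base) / g)
    lo, hi = base - half, base + half
    if fp > hi:
        verdict = "inflated"
    elif fp < lo:
        verdict = "conservative"
    else:
        verdict = "within"
    return EvalResult(method, alpha, fp, g, float(lo), float(hi), verdict, n_excluded)


@dataclass
class PowerEstimate:
    power: float
    n_tests: int
    alpha: float


def evaluate_power(p_values: np.ndarray, alpha: float) -> PowerEstimate:
    """Fraction of tests rejecting at ``alpha`` (genes x replicates pooled)."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if ok.sum() < 1:
        raise ValueError("need at least one p-value")
    return PowerEstimate(float((p[ok] <= alpha).mean()), int(ok.sum()), alpha)


# ---------------------------------------------------------------------------
# benchmark orchestration


@dataclass
class Pretreatment:
    """Per-dataset structures shared across replicates and methods:
    similarity PCA, genetic distances, neighborhoods, local permutations,
    the gene filter and the per-gene CAST carrier matrix."""

    mafs: np.ndarray
    variant_category: str
    pruned_count: int
    pc: PCModel
    graph: NeighborGraph
    perms: PermutationSet | None
    genes: list[str]
    carriers: np.ndarray  # (n, G) int8 CAST indicators
    carrier_counts: np.ndarray  # (G,)
    eigen: SimilarityEigen | None = None
    carriers_rotated: np.ndarray | None = None  # (n, G) U' C for the LMM
    wss_scores: np.ndarray | None = None  # (n, G)


def pretreat(
    dataset: GenotypeDataset,
    variant_set: str = "CV",
    n_pcs: int = 10,
    dist_components: int = 10,
    n_neighbors: int = 30,
    B: int = 500,
    sweeps: int = DEFAULT_SWEEPS,
    perm_seed: int = 0,
    r2_threshold: float = 0.2,
    window: int = 50,
    step: int = 5,
    maf_threshold: float = 0.05,
    min_carriers: int = 10,
    need_perms: bool = True,
    need_lmm: bool = True,
    need_wss: bool = False,
) -> Pretreatment:
    """One-off structure computation for a dataset (reused by every
    replicate): variant classes, LD pruning, similarity matrix, PCA,
    distances, neighbor graph, local permutations, gene filter and carrier
    matrix."""
    mafs = compute_maf(dataset)
    sets = classify_variants(mafs, dataset.variants["private"].to_numpy())
    chosen = sets[variant_set]
    if len(chosen) == 0:
        raise ValueError(f"variant set {variant_set} is empty")
    pruned = ld_prune(dataset, chosen, r2_threshold, window, step, mafs=mafs)
    norm = normalize_genotypes(dataset, pruned)
    sim = similarity_matrix(norm)
    n_comp = min(max(n_pcs, dist_components), dataset.n_samples - 1)
    pc = pca(sim, n_comp)
    d2 = genetic_distance(pc, K=min(dist_components, n_comp))
    graph = nearest_neighbors(d2, N=n_neighbors)
    perms = sample_local_permutations(graph, B, perm_seed, sweeps) if need_perms else None

    genes = []
    carrier_cols = []
    counts = []
    wss_cols = [] if need_wss else None
    for gene in dataset.variants["gene"].unique():
        sel = select_gene_variants(dataset, gene, maf_threshold, mafs)
        if sel.carrier_count < min_carriers:
            continue
        genes.append(gene)
        carrier_cols.append((sel.minor_dosage.sum(axis=1) > 0).astype(np.int8))
        counts.append(sel.carrier_count)
        if need_wss:
            wss_cols.append(wss_score(sel).values.astype(np.float32))
    if not genes:
        raise ValueError("no gene passes the carrier filter")
    carriers = np.column_stack(carrier_cols)
    eigen = SimilarityEigen.from_similarity(sim) if need_lmm else None
    rotated = eigen.u.T @ carriers.astype(float) if need_lmm else None
    return Pretreatment(
        mafs=mafs,
        variant_category=variant_set,
        pruned_count=len(pruned),
        pc=pc,
        graph=graph,
        perms=perms,
        genes=genes,
        carriers=carriers,
        carrier_counts=np.asarray(counts),
        eigen=eigen,
        carriers_rotated=rotated,
        wss_scores=np.column_stack(wss_cols) if need_wss else None,
    )


def _parse_method(name: str) -> tuple[str, int | None]:
    """Return (kind, m) where kind in {CAST, WSS, PC, LMM, LocPerm}."""
    m = re.fullmatch(r"PC(\d+)(?:_[A-Z]+)?", name)
    if m:
        return "PC", int(m.group(1))
    base = name.split("_")[0]
    if base not in {"CAST", "WSS", "LMM", "LocPerm"}:
        raise ValueError(f"unknown method {name!r}")
    return base, None


def _standardized_pcs(pc: PCModel, m: int) -> np.ndarray:
    cov = pc.scores[:, :m]
    sd = cov.std(axis=0)
    sd[sd == 0] = 1.0
    return (cov - cov.mean(axis=0)) / sd


def _cast_scan(y: np.ndarray, carriers: np.ndarray) -> np.ndarray:
    """Closed-form unadjusted CAST p-values for every gene at once."""
    y = np.asarray(y, dtype=float)
    n = y.size
    nc = carriers.sum(axis=0).astype(float)
    a = y @ carriers.astype(float)
    lrt, _ = cast_lrt_from_counts(np.full_like(nc, n), float(y.sum()), nc, a)
    return stats.chi2.sf(lrt, 1)


def _pc_scan(y: np.ndarray, carriers: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """PC-adjusted logistic LRT p-values per gene (null fitted once)."""
    n = y.size
    ones = np.ones((n, 1))
    x_null = np.concatenate([ones, cov], axis=1)
    _, null_ll, null_conv = _logit_fit(x_null, y.astype(float))
    out = np.empty(carriers.shape[1])
    x_alt = np.concatenate([ones, np.zeros((n, 1)), cov], axis=1)
    for g in range(carriers.shape[1]):
        if not null_conv:
            out[g] = np.nan
            continue
        x_alt[:, 1] = carriers[:, g]
        beta, alt_ll, conv = _logit_fit(x_alt, y.astype(float))
        if not conv or abs(beta[1]) > 30.0:
            out[g] = np.nan
        else:
            out[g] = stats.chi2.sf(max(2.0 * (alt_ll - null_ll), 0.0), 1)
    return out


def _lmm_scan(y: np.ndarray, pre: Pretreatment) -> np.ndarray:
    """Mixed-model LRT p-values per gene, reusing the eigenbasis and the
    (gene-independent) null fit."""
    eig = pre.eigen
    ystar = eig.rotate(y.astype(float))
    ones_star = eig.rotate(np.ones(y.size))
    null = _fit_rotated(ystar, ones_star[:, None], eig.d)
    out = np.empty(pre.carriers.shape[1])
    for g in range(pre.carriers.shape[1]):
        x_alt = np.column_stack([ones_star, pre.carriers_rotated[:, g]])
        alt = _fit_rotated(ystar, x_alt, eig.d)
        out[g] = stats.chi2.sf(max(2.0 * (alt.loglik - null.loglik), 0.0), 1)
    return out


def _wss_scan(y: np.ndarray, pre: Pretreatment) -> np.ndarray:
    yf = y.astype(float)
    null_ll = _intercept_only_ll(yf)
    out = np.empty(pre.wss_scores.shape[1])
    for g in range(pre.wss_scores.shape[1]):
        res = logistic_lrt(yf, pre.wss_scores[:, g].astype(float), None, "WSS", null_ll)
        out[g] = res.p
    return out


def _method_tag(kind: str, m: int | None, category: str) -> str:
    if kind == "PC":
        return f"PC{m}_{category}"
    if kind == "LMM":
        return f"LMM_{category}"
    return kind


@dataclass
class BenchmarkResult:
    """Long table of per-gene p-values plus evaluation helpers."""

    pvalues: pd.DataFrame  # columns: replicate, gene, method, p
    scenario: str
    pretreatment: Pretreatment

    def evaluate(self, alpha: float, n_methods: int | None = None) -> pd.DataFrame:
        methods = list(self.pvalues["method"].unique())
        if n_methods is None:
            n_methods = len(methods)
        rows = []
        for tag in methods:
            p = self.pvalues.loc[self.pvalues["method"] == tag, "p"].to_numpy()
            res = evaluate_type1(p, alpha, n_methods, tag)
            rows.append(res.__dict__)
        return pd.DataFrame(rows)


def run_benchmark(
    dataset: GenotypeDataset,
    spec: ScenarioSpec,
    methods=("CAST", "PC3", "LMM", "LocPerm"),
    replicates: int = 10,
    seed: int = 0,
    pretreatment: Pretreatment | None = None,
    **pretreat_kwargs,
) -> BenchmarkResult:
    """Null-hypothesis benchmark: per replicate, assign scenario phenotypes
    and test every filtered gene with every method.

    Structure/permutation pretreatment is computed once per dataset and
    reused across replicates.  Replicate phenotype seeds are derived
    deterministically from ``seed`` (seed + 1 + replicate index; the
    permutation sampler uses ``seed`` itself).
    """
    parsed = [_parse_method(m) for m in methods]
    if pretreatment is None:
        pretreat_kwargs.setdefault("perm_seed", seed)
        pretreatment = pretreat(
            dataset,
            need_perms=any(k == "LocPerm" for k, _ in parsed),
            need_lmm=any(k == "LMM" for k, _ in parsed),
            need_wss=any(k == "WSS" for k, _ in parsed),
            **pretreat_kwargs,
        )
    pre = pretreatment
    labels = dataset.subpop_labels
    genes = np.asarray(pre.genes)

    frames = []
    for r in range(replicates):
        y = assign_null_phenotypes(labels, spec, replicate_seed=seed + 1 + r)
        for (kind, m), name in zip(parsed, methods):
            if kind == "CAST":
                p = _cast_scan(y, pre.carriers)
            elif kind == "PC":
                cov = _standardized_pcs(pre.pc, m)
                p = _pc_scan(y, pre.carriers, cov)
            elif kind == "LMM":
                p = _lmm_scan(y, pre)
            elif kind == "WSS":
                p = _wss_scan(y, pre)
            else:  # LocPerm
                p = locperm_scan(y, pre.carriers, pre.perms)
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": r,
                        "gene": genes,
                        "method": _method_tag(kind, m, pre.variant_category),
                        "p": p,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return BenchmarkResult(table, spec.name, pre)


def run_power(
    dataset: GenotypeDataset,
    spec: ScenarioSpec,
    power_genes: list[PowerGene],
    methods=("CAST", "PC3", "LMM", "LocPerm"),
    rrs=(1, 2, 3, 4),
    replicates: int = 100,
    seed: int = 0,
    pretreatment: Pretreatment | None = None,
    **pretreat_kwargs,
) -> pd.DataFrame:
    """Power study: per gene / RR / replicate, draw penetrance phenotypes
    and test the causal gene with each method.

    Returns a long table (gene, rr, replicate, method, p); summarize with
    :func:`evaluate_power`.
    """
    parsed = [_parse_method(m) for m in methods]
    if pretreatment is None:
        pretreat_kwargs.setdefault("perm_seed", seed)
        pretreatment = pretreat(
            dataset,
            need_perms=any(k == "LocPerm" for k, _ in parsed),
            need_lmm=any(k == "LMM" for k, _ in parsed),
            **pretreat_kwargs,
        )
    pre = pretreatment
    labels = dataset.subpop_labels
    gene_col = {g: i for i, g in enumerate(pre.genes)}

    rows = []
    for gi, pg in enumerate(power_genes):
        if pg.gene not in gene_col:
            raise ValueError(f"power gene {pg.gene} does not pass the carrier filter")
        col = gene_col[pg.gene]
        carrier_test = pre.carriers[:, [col]]
        for ri, rr in enumerate(rrs):
            for rep in range(replicates):
                rep_seed = np.random.SeedSequence([seed, gi, ri, rep])
                y = simulate_alt_phenotypes(labels, pg.causal_carrier, spec, rr, rep_seed)
                if y.min() == y.max():  # degenerate draw; count as no signal
                    continue
                for (kind, m), name in zip(parsed, methods):
                    if kind == "CAST":
                        p = float(_cast_scan(y, carrier_test)[0])
                    elif kind == "PC":
                        cov = _standardized_pcs(pre.pc, m)
                        p = float(_pc_scan(y, carrier_test, cov)[0])
                    elif kind == "LMM":
                        eig = pre.eigen
                        ystar = eig.rotate(y.astype(float))
                        ones_star = eig.rotate(np.ones(y.size))
                        null = _fit_rotated(ystar, ones_star[:, None], eig.d)
                        x_alt = np.column_stack([ones_star, pre.carriers_rotated[:, col]])
                        alt = _fit_rotated(ystar, x_alt, eig.d)
                        p = float(
                            stats.chi2.sf(max(2.0 * (alt.loglik - null.loglik), 0.0), 1)
                        )
                    else:
                        p = float(locperm_scan(y, carrier_test, pre.perms)[0])
                    rows.append(
                        {
                            "gene": pg.gene,
                            "rr": rr,
                            "replicate": rep,
                            "method": _method_tag(kind, m, pre.variant_category),
                            "p": p,
                        }
                    )
    return pd.DataFrame(rows)


def run_small_sample_power(
    dataset: GenotypeDataset,
    pretreatment: Pretreatment,
    design: SmallSampleDesign,
    power_genes: list[PowerGene],
    rr: float = 4.0,
    replicates: int = 25,
    seed: int = 0,
    methods=("CAST", "PC3", "LocPerm"),
    B: int = 500,
    n_neighbors: int = 30,
    maf_threshold: float = 0.05,
    max_redraws: int = 20,
) -> pd.DataFrame:
    """Power of a few-cases design (e.g. 50 cases + an external control
    panel) under the gene-level penetrance model.

    Per replicate, phenotypes are simulated on the full cohort with the
    subgroup disease frequencies implied by the design, then the analyzed
    subset (cases from the case pool, disease-free controls from the
    control pool) is drawn and each gene re-tested inside the subset
    (variant selection at MAF <= 5% *within the analyzed sample*).
    LocPerm neighborhoods come from the full-cohort PC coordinates
    restricted to the subset; the permutation set is resampled per
    replicate since the subset changes.  ``rr=1`` gives the design's null
    calibration.
    """
    labels = np.asarray(dataset.subpop_labels)
    subpops, sizes = np.unique(labels, return_counts=True)
    size_of = dict(zip(subpops, sizes))
    n_total = labels.size

    # expected analyzed-sample composition -> subgroup disease frequencies
    k_by_subpop: dict[str, float] = {}
    for sp in subpops:
        if design.case_pool is None:
            exp_cases = design.n_cases * size_of[sp] / n_total
        else:
            exp_cases = design.n_cases if sp == design.case_pool else 0.0
        if design.control_pool is None:
            exp_controls = design.n_controls * size_of[sp] / n_total
        else:
            exp_controls = design.n_controls if sp == design.control_pool else 0.0
        exp_n = exp_cases + exp_controls
        k_by_subpop[sp] = exp_cases / exp_n if exp_n > 0 else 0.0

    parsed = [_parse_method(m) for m in methods]
    w_coords = pretreatment.pc.scores[:, :10] * np.sqrt(pretreatment.pc.eigenvalues[:10])
    case_pool_idx = _pool_indices(labels, design.case_pool)
    control_pool_idx = _pool_indices(labels, design.control_pool)

    rows = []
    for gi, pg in enumerate(power_genes):
        gene_cols = dataset.gene_variant_indices(pg.gene)
        for rep in range(replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, gi, rep]))
            cases = controls = None
            for _ in range(max_redraws):
                y_full = _phenotypes_from_penetrance(
                    labels, pg.causal_carrier, k_by_subpop, rr, rng
                )
                case_cand = case_pool_idx[y_full[case_pool_idx] == 1]
                ctrl_cand = control_pool_idx[y_full[control_pool_idx] == 0]
                if case_cand.size >= design.n_cases and ctrl_cand.size >= design.n_controls:
                    cases = rng.choice(case_cand, size=design.n_cases, replace=False)
                    controls = rng.choice(ctrl_cand, size=design.n_controls, replace=False)
                    break
            if cases is None:
                raise ValueError(
                    f"design {design.name}: could not draw {design.n_cases} cases "
                    f"after {max_redraws} phenotype redraws (gene {pg.gene}, RR={rr})"
                )
            subset = np.concatenate([cases, controls])
            y = np.concatenate(
                [np.ones(cases.size, dtype=np.int8), np.zeros(controls.size, dtype=np.int8)]
            )

            # re-select the gene's rare variants within the analyzed sample
            g_sub = dataset.genotypes[np.ix_(subset, gene_cols)]
            sub_maf = compute_maf(g_sub)
            keep = np.isfinite(sub_maf) & (sub_maf > 0) & (sub_maf <= maf_threshold)
            if not keep.any():
                continue
            g_keep = g_sub[:, keep].astype(float)
            g_keep[g_keep < 0] = 0
            alt_freq = g_keep.mean(axis=0) / 2.0
            flip = alt_freq > 0.5
            g_keep[:, flip] = 2 - g_keep[:, flip]
            carrier = (g_keep.sum(axis=1) > 0).astype(np.int8)[:, None]

            perms = None
            for (kind, m), name in zip(parsed, methods):
                if kind == "CAST":
                    p = float(_cast_scan(y, carrier)[0])
                elif kind == "PC":
                    sub_scores = PCModel(
                        pretreatment.pc.scores[subset],
                        pretreatment.pc.eigenvalues,
                        pretreatment.pc.category,
                    )
                    cov = _standardized_pcs(sub_scores, m)
                    p = float(_pc_scan(y, carrier, cov)[0])
                elif kind == "LocPerm":
                    if perms is None:
                        w_sub = w_coords[subset]
                        sq = (w_sub**2).sum(axis=1)
                        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * w_sub @ w_sub.T, 0)
                        np.fill_diagonal(d2, 0.0)
                        graph = nearest_neighbors(d2, N=n_neighbors)
                        perms = sample_local_permutations(
                            graph, B, seed=int(rng.integers(2**31))
                        )
                    p = float(locperm_scan(y, carrier, perms)[0])
                else:
                    raise ValueError(f"method {name} not supported for small-sample designs")
                rows.append(
                    {
                        "design": design.name,
                        "gene": pg.gene,
                        "rr": rr,
                        "replicate": rep,
                        "method": _method_tag(kind, m, pretreatment.variant_category),
                        "p": p,
                    }
                )
    return pd.DataFrame(rows)
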