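"""Gene-level burden scores and the (optionally PC-adjusted) logistic LRT.

Two collapsing scores are provided: the CAST indicator (1 if a sample
carries at least one rare allele in the gene, 0 otherwise) and the
Madsen-Browning weighted sum (WSS), ``z_i = sum_k w_k x_ik`` with
``w_k = 1 / sqrt(MAF_k (1 - MAF_k))``.  Association is tested by a
likelihood-ratio test in the logistic model

    logit P(Y = 1) = alpha + beta_g Z_g (+ gamma_1 PC_1 + ... + gamma_m PC_m)

where the null drops only ``beta_g``; the LRT is referred to a chi-square
with one degree of freedom.

Gene-test variant selection keeps biallelic variants with a folded MAF at
or below 5% in the analyzed sample, *including* private variants (private
variants are excluded only from similarity matrices, not from testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import MISSING, GenotypeDataset
from .structure import PCModel, compute_maf, unfolded_freq

__all__ = [
    "BurdenScore",
    "GeneTestResult",
    "GeneSelection",
    "select_gene_variants",
    "gene_filter",
    "cast_score",
    "wss_score",
    "logistic_lrt",
    "pc_adjusted_test",
    "cast_lrt_from_counts",
    "results_table",
]

MAX_ABS_BETA = 30.0  # coefficient magnitude treated as (quasi-)separation
MAX_IRLS_ITER = 100
LL_TOL = 1e-8


@dataclass
class BurdenScore:
    """Per-sample collapsed genetic score for one gene."""

    gene: str
    values: np.ndarray
    kind: str  # "CAST" or "WSS"
    weights: np.ndarray | None = None
    variant_indices: np.ndarray | None = None


@dataclass
class GeneTestResult:
    """Outcome of one gene-level association test."""

    gene: str
    method: str
    lrt: float
    p: float
    sign: int
    beta: float = np.nan
    converged: bool = True
    n_variants: int = 0
    n_carriers: int = 0


@dataclass
class GeneSelection:
    """Variants of a gene retained for testing, as minor-allele dosages."""

    gene: str
    variant_indices: np.ndarray
    minor_dosage: np.ndarray = field(repr=False, default=None)  # (n, m)
    mafs: np.ndarray | None = None
    carrier_count: int = 0


def select_gene_variants(
    dataset: GenotypeDataset,
    gene: str,
    maf_threshold: float = 0.05,
    mafs: np.ndarray | None = None,
) -> GeneSelection:
    """Select the gene's rare variants (MAF <= threshold, private included).

    Dosages are flipped to count the minor allele where the ALT allele is
    the major one, so "carrier" always means carrier of at least one rare
    allele.  Monomorphic variants (MAF 0: no carriers, undefined WSS
    weight) are dropped.  Missing calls count as non-carrying.  An empty
    selection is returned as such (carrier count zero), not an error.
    """
    idx = dataset.gene_variant_indices(gene)
    if mafs is None:
        gene_mafs = compute_maf(dataset.genotypes[:, idx])
    else:
        gene_mafs = np.asarray(mafs)[idx]
    keep = np.isfinite(gene_mafs) & (gene_mafs > 0.0) & (gene_mafs <= maf_threshold)
    idx = idx[keep]
    sel_maf = gene_mafs[keep]
    g = dataset.genotypes[:, idx].astype(np.int8)
    f = unfolded_freq(g)
    flip = f > 0.5
    md = np.where(g == MISSING, 0, g).astype(np.int8)
    md[:, flip] = np.where(g[:, flip] == MISSING, 0, 2 - g[:, flip])
    carriers = int((md.sum(axis=1) > 0).sum())
    return GeneSelection(gene, idx, md, sel_maf, carriers)


def gene_filter(
    dataset: GenotypeDataset,
    min_carriers: int = 10,
    maf_threshold: float = 0.05,
    mafs: np.ndarray | None = None,
) -> list[str]:
    """Genes with at least ``min_carriers`` rare-variant carriers."""
    if mafs is None:
        mafs = compute_maf(dataset)
    genes = dataset.variants["gene"].unique()
    out = []
    for gene in genes:
        sel = select_gene_variants(dataset, gene, maf_threshold, mafs)
        if sel.carrier_count >= min_carriers:
            out.append(gene)
    return out


def cast_score(selection: GeneSelection) -> BurdenScore:
    """CAST indicator: 1 iff the sample carries >= 1 selected rare allele."""
    values = (selection.minor_dosage.sum(axis=1) > 0).astype(np.int8)
    return BurdenScore(selection.gene, values, "CAST", None, selection.variant_indices)


def wss_score(selection: GeneSelection) -> BurdenScore:
    """Madsen-Browning weighted sum: ``sum_k x_ik / sqrt(MAF_k (1-MAF_k))``.

    Weights use the analyzed sample's folded MAFs; a monomorphic selected
    variant (MAF 0) has an undefined weight and raises.
    """
    mafs = np.asarray(selection.mafs, dtype=float)
    if np.any(~np.isfinite(mafs)) or np.any(mafs <= 0.0):
        raise ValueError(f"gene {selection.gene}: monomorphic variant in WSS selection")
    w = 1.0 / np.sqrt(mafs * (1.0 - mafs))
    values = selection.minor_dosage @ w
    return BurdenScore(selection.gene, values, "WSS", w, selection.variant_indices)


def results_table(results) -> "pd.DataFrame":
    """Collect gene test results into the standard tab-friendly table
    (gene, method, n_variants, n_carriers, lrt, sign, p)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "method": r.method,
                "n_variants": r.n_variants,
                "n_carriers": r.n_carriers,
                "lrt": r.lrt,
                "sign": r.sign,
                "p": r.p,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# logistic likelihood machinery


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _logit_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """IRLS fit of a logistic regression; returns (beta, loglik, converged)."""
    n, q = X.shape
    beta = np.zeros(q)
    ll = _bernoulli_ll(y, X @ beta)
    for _ in range(MAX_IRLS_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1.0 - p), 1e-10)
        z = eta + (y - p) / w
        xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ xw, xw.T @ z)
        except np.linalg.LinAlgError:
            return beta, ll, False
        ll_new = _bernoulli_ll(y, X @ beta_new)
        beta = beta_new
        if abs(ll_new - ll) < LL_TOL:
            return beta, ll_new, True
        ll = ll_new
    return beta, ll, False


def _intercept_only_ll(y: np.ndarray) -> float:
    n = y.size
    n1 = y.sum()
    if n1 == 0 or n1 == n:
        return 0.0
    return float(n1 * np.log(n1 / n) + (n - n1) * np.log(1.0 - n1 / n))


def logistic_lrt(
    phenotypes: np.ndarray,
    score: BurdenScore | np.ndarray,
    covariates: np.ndarray | None = None,
    method: str | None = None,
    null_ll: float | None = None,
) -> GeneTestResult:
    """Logistic likelihood-ratio test of the burden score.

    The alternative fits intercept + score (+ covariates); the null drops
    only the score coefficient.  ``null_ll`` allows reusing a precomputed
    null log-likelihood (the null does not depend on the gene).  Complete
    separation or non-convergence yields a flagged result with ``p`` NaN;
    a constant score yields LRT 0, p 1.
    """
    y = np.asarray(phenotypes, dtype=float)
    if isinstance(score, BurdenScore):
        gene, kind, z = score.gene, score.kind, np.asarray(score.values, dtype=float)
    else:
        gene, kind, z = "", "score", np.asarray(score, dtype=float)
    if method is None:
        method = kind
    n_unique = np.unique(y)
    if not np.all(np.isin(n_unique, [0.0, 1.0])) or n_unique.size < 2:
        raise ValueError("phenotypes must be binary with both classes present")

    if np.ptp(z) == 0.0:
        return GeneTestResult(gene, method, 0.0, 1.0, 0, 0.0, True)

    n = y.size
    ones = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        x_null = np.concatenate([ones, cov], axis=1)
        x_alt = np.concatenate([ones, z[:, None], cov], axis=1)
        if null_ll is None:
            _, null_ll, null_conv = _logit_fit(x_null, y)
            if not null_conv:
                return GeneTestResult(gene, method, np.nan, np.nan, 0, np.nan, False)
    else:
        x_alt = np.concatenate([ones, z[:, None]], axis=1)
        if null_ll is None:
            null_ll = _intercept_only_ll(y)

    beta, alt_ll, conv = _logit_fit(x_alt, y)
    beta_g = float(beta[1])
    if not conv or abs(beta_g) > MAX_ABS_BETA:
        return GeneTestResult(gene, method, np.nan, np.nan, int(np.sign(beta_g)), beta_g, False)
    lrt = max(2.0 * (alt_ll - null_ll), 0.0)
    p = float(stats.chi2.sf(lrt, 1))
    return GeneTestResult(gene, method, lrt, p, int(np.sign(beta_g)), beta_g, True)


def pc_adjusted_test(
    phenotypes: np.ndarray,
    score: BurdenScore | np.ndarray,
    pc: PCModel,
    m: int = 3,
    null_ll: float | None = None,
) -> GeneTestResult:
    """Logistic LRT adjusted for the first ``m`` principal components.

    ``m = 0`` reduces to the unadjusted test.  PC covariate columns are
    standardized internally (a linear reparameterization; the LRT is
    unchanged).
    """
    if m > pc.n_components:
        raise ValueError(f"m={m} exceeds available components ({pc.n_components})")
    tag = f"PC{m}_{pc.category}"
    if m == 0:
        res = logistic_lrt(phenotypes, score, None, tag, null_ll)
        return res
    cov = pc.scores[:, :m]
    sd = cov.std(axis=0)
    sd[sd == 0] = 1.0
    cov = (cov - cov.mean(axis=0)) / sd
    return logistic_lrt(phenotypes, score, cov, tag, null_ll)


# ---------------------------------------------------------------------------
# closed-form 2x2 CAST deviance (vectorized)


def _xlogx(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def cast_lrt_from_counts(n, n1, nc, a):
    """Unadjusted logistic CAST LRT from 2x2 table counts, vectorized.

    Parameters are total samples ``n``, cases ``n1``, carriers ``nc`` and
    carrier-cases ``a``.  The maximized alternative likelihood of the
    logistic model with a binary score is the saturated two-binomial fit,
    so the LRT has this closed form (identical to the IRLS fit away from
    boundary cells, and its well-defined limit on them).

    Returns ``(lrt, sign)`` where ``sign`` is the sign of the carrier
    effect (sign of the fitted log odds ratio).
    """
    n = np.asarray(n, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    nc = np.asarray(nc, dtype=float)
    a = np.asarray(a, dtype=float)
    b = nc - a  # carrier controls
    c = n1 - a  # non-carrier cases
    d = n - nc - c  # non-carrier controls
    ll_alt = (
        _xlogx(a) + _xlogx(b) + _xlogx(c) + _xlogx(d) - _xlogx(nc) - _xlogx(n - nc)
    )
    ll_null = _xlogx(n1) + _xlogx(n - n1) - _xlogx(n)
    lrt = 2.0 * (ll_alt - ll_null)
    lrt = np.maximum(lrt, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_c = np.where(nc > 0, a / nc, 0.0)
        rate_n = np.where(n - nc > 0, c / (n - nc), 0.0)
    sign = np.sign(rate_c - rate_n)
    degenerate = (nc <= 0) | (nc >= n)
    lrt = np.where(degenerate, 0.0, lrt)
    sign = np.where(degenerate, 0.0, sign)
    return lrt, sign
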