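"""Linear mixed model association test with a genetic-relatedness random
effect.

The model is ``Y = X b + u + e`` with ``u ~ MVN(0, tau S)`` and
``e ~ MVN(0, sigma^2 I)``, where ``S`` is a genetic similarity matrix.  The
binary phenotype is treated as quantitative (the standard fast-LMM
linearization; an approximation documented in the methods note).  Writing
``delta = sigma^2 / tau``, a single eigendecomposition ``S = U D U'``
rotates the model to independent residuals with variances
``tau (d_i + delta)``; ``b`` and ``tau`` are profiled out in closed form
and the maximum-likelihood fit reduces to a one-dimensional search over
``log delta`` on ``[-10, 10]`` (coarse grid plus bounded refinement within
the best bracket).

Both the null (intercept only) and the alternative (intercept + burden
score) re-optimize the variance components, so the gene-level LRT is a
genuine likelihood ratio, referred to a chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .burden import BurdenScore, GeneTestResult
from .structure import SimilarityMatrix

__all__ = ["LMMFit", "SimilarityEigen", "lmm_fit", "lmm_lrt"]

LOG_DELTA_BOUNDS = (-10.0, 10.0)
N_GRID = 50
PSD_TOL = 1e-8


@dataclass
class SimilarityEigen:
    """Cached eigendecomposition of a similarity matrix (``S = U D U'``)."""

    d: np.ndarray  # eigenvalues, ascending, clipped at 0
    u: np.ndarray  # eigenvectors (columns)

    @classmethod
    def from_similarity(cls, sim) -> "SimilarityEigen":
        s = sim.matrix if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
        if s.shape[0] != s.shape[1] or not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("similarity matrix must be square and symmetric")
        d, u = np.linalg.eigh((s + s.T) / 2.0)
        scale = max(abs(d[0]), abs(d[-1]), 1.0)
        if d[0] < -PSD_TOL * scale:
            raise ValueError(
                f"similarity matrix is not PSD within tolerance (min eigenvalue {d[0]:.3g})"
            )
        return cls(np.maximum(d, 0.0), u)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.u.T @ a


@dataclass
class LMMFit:
    """Maximum-likelihood fit of the similarity-matrix mixed model."""

    beta: np.ndarray
    tau: float
    sigma2: float
    log_delta: float
    loglik: float
    boundary: bool

    @property
    def delta(self) -> float:
        return float(np.exp(self.log_delta))

    @property
    def genetic_fraction(self) -> float:
        """tau / (tau + sigma^2), the variance share of the random effect."""
        return self.tau / (self.tau + self.sigma2)


def _profile_fit(ystar: np.ndarray, xstar: np.ndarray, d: np.ndarray, log_delta: float):
    """Profiled ML at fixed ``log delta``: GLS beta, tau-hat, log-likelihood."""
    n = ystar.size
    w = 1.0 / (d + np.exp(log_delta))
    xw = xstar * w[:, None]
    a = xstar.T @ xw
    b = xw.T @ ystar
    try:
        beta = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(xstar, ystar, rcond=None)[0]
    r = ystar - xstar @ beta
    rss_w = float(np.sum(w * r * r))
    tau = max(rss_w / n, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * tau) - np.sum(np.log(w)) + n)
    return beta, tau, float(ll)


def _fit_rotated(
    ystar: np.ndarray,
    xstar: np.ndarray,
    d: np.ndarray,
    fix_log_delta: float | None = None,
) -> LMMFit:
    lo, hi = LOG_DELTA_BOUNDS
    if fix_log_delta is not None:
        beta, tau, ll = _profile_fit(ystar, xstar, d, fix_log_delta)
        return LMMFit(beta, tau, tau * np.exp(fix_log_delta), fix_log_delta, ll, False)
    grid = np.linspace(lo, hi, N_GRID)
    lls = np.array([_profile_fit(ystar, xstar, d, g)[2] for g in grid])
    i = int(np.argmax(lls))
    left = grid[max(i - 1, 0)]
    right = grid[min(i + 1, N_GRID - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profile_fit(ystar, xstar, d, g)[2],
        bounds=(left, right),
        method="bounded",
        options={"xatol": 1e-7},
    )
    candidates = [(lls[i], grid[i]), (-res.fun, float(res.x))]
    ll, log_delta = max(candidates)
    beta, tau, ll = _profile_fit(ystar, xstar, d, log_delta)
    boundary = i in (0, N_GRID - 1)
    return LMMFit(beta, tau, tau * np.exp(log_delta), log_delta, ll, boundary)


def _as_eigen(s) -> SimilarityEigen:
    if isinstance(s, SimilarityEigen):
        return s
    return SimilarityEigen.from_similarity(s)


def lmm_fit(
    phenotypes: np.ndarray,
    design: np.ndarray,
    similarity,
    fix_log_delta: float | None = None,
) -> LMMFit:
    """ML fit of ``Y = design b + u + e`` with ``u ~ MVN(0, tau S)``.

    ``similarity`` may be a :class:`SimilarityMatrix`, a raw symmetric PSD
    array, or a precomputed :class:`SimilarityEigen` (reused across genes).
    An optimum on the ``log delta`` search bound is returned flagged
    (``boundary=True``), not rejected.
    """
    eig = _as_eigen(similarity)
    y = np.asarray(phenotypes, dtype=float)
    x = np.atleast_2d(np.asarray(design, dtype=float))
    if x.shape[0] != y.size:
        x = x.T
    return _fit_rotated(eig.rotate(y), eig.rotate(x), eig.d, fix_log_delta)


def lmm_lrt(
    phenotypes: np.ndarray,
    score: BurdenScore | np.ndarray,
    similarity,
    reuse_null_delta: bool = False,
    null_fit: LMMFit | None = None,
) -> GeneTestResult:
    """Gene-level mixed-model LRT (null drops only the score coefficient).

    By default both fits re-optimize ``delta``; ``reuse_null_delta=True``
    is a faster approximation that fixes the alternative's ``delta`` at the
    null's estimate.  ``null_fit`` allows reusing the (gene-independent)
    null model across genes.
    """
    eig = _as_eigen(similarity)
    y = np.asarray(phenotypes, dtype=float)
    if isinstance(score, BurdenScore):
        gene, kind, z = score.gene, score.kind, np.asarray(score.values, dtype=float)
    else:
        gene, kind, z = "", "score", np.asarray(score, dtype=float)
    method = f"LMM_{kind}" if kind != "score" else "LMM"

    if np.ptp(z) == 0.0:
        return GeneTestResult(gene, method, 0.0, 1.0, 0, 0.0, True)

    ystar = eig.rotate(y)
    ones_star = eig.rotate(np.ones_like(y))
    if null_fit is None:
        null_fit = _fit_rotated(ystar, ones_star[:, None], eig.d)
    x_alt = np.column_stack([ones_star, eig.rotate(z)])
    alt = _fit_rotated(
        ystar, x_alt, eig.d, fix_log_delta=null_fit.log_delta if reuse_null_delta else None
    )
    lrt = max(2.0 * (alt.loglik - null_fit.loglik), 0.0)
    p = float(stats.chi2.sf(lrt, 1))
    beta_g = float(alt.beta[1])
    return GeneTestResult(gene, method, lrt, p, int(np.sign(beta_g)), beta_g, True)
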