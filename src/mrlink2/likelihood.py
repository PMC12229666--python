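"""The MR-link-2 likelihood: eigen-space preparation, optimization, inference.

The model treats the multivariable SNP effects on the exposure and outcome
as random (infinitesimal architecture): gamma_X ~ N(0, sigma2x) per SNP,
gamma_Y ~ N(0, sigma2y) per SNP, with the causal effect ``alpha`` carrying
exposure effects into the outcome. Marginal GWAS effects are then jointly
Gaussian with covariance blocks

    Cov[bX]     = sigma2x * C^2          + C / nX
    Cov[bX, bY] = alpha * sigma2x * C^2
    Cov[bY]     = (alpha^2 sigma2x + sigma2y) * C^2 + C / nY

After rotating into the eigenbasis of C (C = U L U^T, truncated to the
leading components holding ``variance_kept`` of the trace) the 2m-dimensional
density factorizes into independent bivariate Gaussians, one per retained
eigenvalue, which is what :func:`log_likelihood` evaluates. Inference on
``alpha`` (causal effect) and ``sigma2y`` (horizontal pleiotropy) is by
likelihood-ratio tests with one degree of freedom, each against the freely
estimated three-parameter fit.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .io import LDMatrix, MRResult

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class RegionEigen:
    """Truncated eigen-system of a regional LD matrix plus rotated effects.

    ``lambdas`` are the retained eigenvalues (descending, positive), ``U``
    the matching eigenvectors (columns, orthonormal), ``deltaX``/``deltaY``
    the rotated effect vectors U^T beta. ``m_full`` is the SNP count of the
    region before truncation; heritabilities are reported on that scale.
    """

    lambdas: np.ndarray
    U: np.ndarray
    deltaX: np.ndarray
    deltaY: np.ndarray
    nX: float
    nY: float
    m_full: int

    @property
    def m(self) -> int:
        return len(self.lambdas)


@dataclass
class Link2Params:
    """Free parameters of the likelihood; variances are per-SNP quantities."""

    alpha: float
    sigma2x: float
    sigma2y: float


@dataclass
class Link2Fit:
    """Maximized log-likelihoods of the three fits and the derived inference."""

    ll_full: float
    ll_alpha0: float
    ll_sigy0: float
    params_full: Link2Params
    p_alpha: float
    p_h2y: float
    se_alpha: float
    function_evals: int
    converged: bool


@dataclass
class EigenBasis:
    """Truncated eigen-system of one LD matrix, reusable across replicates."""

    lambdas: np.ndarray
    U: np.ndarray
    m_full: int


def ld_eigen_basis(
    C: LDMatrix | np.ndarray, variance_kept: float = 0.99
) -> EigenBasis:
    """Eigendecompose C, keeping the leading components holding
    ``variance_kept`` of the trace.

    Small negative eigenvalues (above -1e-8) from numerical round-off are
    clipped to zero and excluded; more negative ones trigger a warning before
    clipping, since they indicate a correlation matrix that was not positive
    semidefinite.
    """
    Cm = C.C if isinstance(C, LDMatrix) else np.asarray(C, dtype=float)
    lam, U = np.linalg.eigh(Cm)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    if lam[-1] < -1e-8:
        warnings.warn(
            f"LD matrix has negative eigenvalues (min {lam[-1]:.2e}); clipping to 0"
        )
    lam = np.clip(lam, 0.0, None)

    total = lam.sum()
    keep = int(np.searchsorted(np.cumsum(lam), variance_kept * total) + 1)
    keep = min(keep, int((lam > 0).sum()))
    return EigenBasis(lambdas=lam[:keep], U=U[:, :keep], m_full=Cm.shape[0])


def rotate_effects(
    basis: EigenBasis, betaX, betaY, nX: float, nY: float
) -> RegionEigen:
    """Rotate effect vectors into a precomputed eigenbasis."""
    betaX = np.asarray(betaX, dtype=float)
    betaY = np.asarray(betaY, dtype=float)
    if betaX.shape != (basis.m_full,) or betaY.shape != (basis.m_full,):
        raise ValueError("effect vectors are not aligned with C")
    return RegionEigen(
        lambdas=basis.lambdas,
        U=basis.U,
        deltaX=basis.U.T @ betaX,
        deltaY=basis.U.T @ betaY,
        nX=float(nX),
        nY=float(nY),
        m_full=basis.m_full,
    )


def prepare_region(
    betaX,
    betaY,
    C: LDMatrix | np.ndarray,
    nX: float,
    nY: float,
    variance_kept: float = 0.99,
) -> RegionEigen:
    """Eigendecompose C and rotate the effect vectors into component space."""
    return rotate_effects(
        ld_eigen_basis(C, variance_kept=variance_kept), betaX, betaY, nX, nY
    )


def _loglik(alpha, sx2, sy2, lam, dX, dY, nX, nY) -> float:
    """Sum of per-component bivariate Gaussian log-densities.

    Finite for sigma2x > 0 and sigma2y >= 0; the sigma2y = 0 constrained fit
    evaluates this same expression (the covariance stays positive definite
    through the sampling-noise terms lam/n)."""
    u = lam * lam
    s11 = sx2 * u + lam / nX
    s12 = alpha * sx2 * u
    s22 = (alpha * alpha * sx2 + sy2) * u + lam / nY
    det = s11 * s22 - s12 * s12
    if not np.all(np.isfinite(det)) or np.any(det <= 0.0):
        return -np.inf
    quad = (s22 * dX * dX - 2.0 * s12 * dX * dY + s11 * dY * dY) / det
    value = -len(lam) * _LOG2PI - 0.5 * float(np.sum(np.log(det) + quad))
    return value if np.isfinite(value) else -np.inf


def log_likelihood(params: Link2Params, region: RegionEigen) -> float:
    """Log-likelihood of the summary statistics at ``params``."""
    return _loglik(
        params.alpha,
        params.sigma2x,
        params.sigma2y,
        region.lambdas,
        region.deltaX,
        region.deltaY,
        region.nX,
        region.nY,
    )


def _moment_starts(region: RegionEigen) -> tuple[float, float, float]:
    """Method-of-moments initial values for (alpha, sigma2x, sigma2y)."""
    lam, dX, dY = region.lambdas, region.deltaX, region.deltaY
    u = lam * lam
    sx0 = float(np.mean((dX * dX - lam / region.nX) / u))
    sy0 = float(np.mean((dY * dY - lam / region.nY) / u))
    a0 = float(np.sum(dX * dY) / max(np.sum(dX * dX), 1e-300))
    return a0, max(sx0, 1e-10), max(sy0, 1e-12)


_NM_OPTIONS = {"xatol": 1e-4, "fatol": 1e-6, "maxiter": 1000}


def _maximize(fun, starts):
    best = None
    evals = 0
    for s in starts:
        res = minimize(fun, np.asarray(s, dtype=float), method="Nelder-Mead",
                       options=_NM_OPTIONS)
        evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    return best, evals


def fit_region(
    region: RegionEigen,
    compute_se: bool = True,
) -> Link2Fit:
    """Three Nelder-Mead maximizations and likelihood-ratio inference.

    Variance components are optimized on the log scale (positivity without
    constraints); ``alpha`` on the natural scale. Each fit runs from a
    method-of-moments start plus a near-boundary pleiotropy start, keeping
    the best. P values come from one-degree-of-freedom likelihood-ratio
    tests against the free fit, with negative LR statistics (optimizer
    round-off at the boundary) clipped to zero. ``se_alpha`` is derived from
    the numerical curvature of the alpha profile likelihood at the optimum.
    """
    lam, dX, dY = region.lambdas, region.deltaX, region.deltaY
    nX, nY = region.nX, region.nY
    a0, sx0, sy0 = _moment_starts(region)
    lsx0, lsy0 = np.log(sx0), np.log(sy0)
    boundary = -18.0  # log sigma2y start near zero pleiotropy

    def neg_full(t):
        return -_loglik(t[0], np.exp(t[1]), np.exp(t[2]), lam, dX, dY, nX, nY)

    def neg_alpha0(t):
        return -_loglik(0.0, np.exp(t[0]), np.exp(t[1]), lam, dX, dY, nX, nY)

    def neg_sigy0(t):
        return -_loglik(t[0], np.exp(t[1]), 0.0, lam, dX, dY, nX, nY)

    r_a0, e1 = _maximize(neg_alpha0, [[lsx0, lsy0], [lsx0, boundary]])
    r_s0, e2 = _maximize(neg_sigy0, [[a0, lsx0]])
    r_full, e3 = _maximize(
        neg_full, [[a0, lsx0, lsy0], [a0, lsx0, boundary]]
    )
    evals = e1 + e2 + e3
    converged = bool(r_full.success and r_a0.success and r_s0.success)

    ll_full, ll_a0, ll_s0 = -r_full.fun, -r_a0.fun, -r_s0.fun
    # nesting can be violated only by optimizer noise; repair conservatively
    if ll_full < max(ll_a0, ll_s0):
        ll_full = max(ll_full, ll_a0, ll_s0)

    alpha_hat = float(r_full.x[0])
    params = Link2Params(
        alpha=alpha_hat,
        sigma2x=float(np.exp(r_full.x[1])),
        sigma2y=float(np.exp(r_full.x[2])),
    )
    p_alpha = float(chi2.sf(max(2.0 * (ll_full - ll_a0), 0.0), df=1))
    p_h2y = float(chi2.sf(max(2.0 * (ll_full - ll_s0), 0.0), df=1))

    se_alpha = np.nan
    if compute_se:
        se_alpha = _profile_se(r_full, ll_full, lam, dX, dY, nX, nY)

    return Link2Fit(
        ll_full=ll_full,
        ll_alpha0=ll_a0,
        ll_sigy0=ll_s0,
        params_full=params,
        p_alpha=p_alpha,
        p_h2y=p_h2y,
        se_alpha=se_alpha,
        function_evals=evals,
        converged=converged,
    )


def _profile_se(r_full, ll_full, lam, dX, dY, nX, nY) -> float:
    """Standard error of alpha from the profile-likelihood curvature.

    Re-optimizes the variance components at alpha +/- h (warm-started from
    the full optimum) and applies a central second difference. The step is
    scaled from a crude Wald guess so the profile drops by O(1) log-units.
    """
    alpha_hat = float(r_full.x[0])
    nuis = r_full.x[1:]

    def profile(a):
        res = minimize(
            lambda t: -_loglik(a, np.exp(t[0]), np.exp(t[1]), lam, dX, dY, nX, nY),
            nuis, method="Nelder-Mead", options=_NM_OPTIONS,
        )
        return -res.fun

    h = 0.02 * max(abs(alpha_hat), 0.05)
    ll_lo, ll_hi = profile(alpha_hat - h), profile(alpha_hat + h)
    curv = (ll_hi - 2.0 * ll_full + ll_lo) / (h * h)
    if curv >= 0:
        return np.nan
    return float(1.0 / np.sqrt(-curv))


def run_mr_link2(
    betaX,
    betaY,
    C: LDMatrix | np.ndarray,
    nX: float,
    nY: float,
    variance_kept: float = 0.99,
    region_bounds: tuple[str, int, int] | None = None,
    compute_se: bool = True,
) -> MRResult:
    """Convenience wrapper: prepare the eigen-system, fit, return an MRResult."""
    eig = prepare_region(betaX, betaY, C, nX, nY, variance_kept=variance_kept)
    fit = fit_region(eig, compute_se=compute_se)
    m = eig.m_full
    return MRResult(
        method="mr_link2",
        alpha_hat=fit.params_full.alpha,
        se_alpha=fit.se_alpha,
        p_alpha=fit.p_alpha,
        h2x_hat=m * fit.params_full.sigma2x,
        h2y_hat=m * fit.params_full.sigma2y,
        p_h2y=fit.p_h2y,
        m_snps=m,
        region=region_bounds,
        converged=fit.converged,
    )
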