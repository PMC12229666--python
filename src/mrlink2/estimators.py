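"""Benchmark cis-MR estimators: Wald ratio, IVW, IVW-LD and PCA-based MR.

These operate on harmonized standardized effects. The IVW family uses
selected (approximately independent) instruments; the LD-aware variants
additionally take the instrument correlation submatrix and generalize the
weighting to a GLS form. The PCA variant follows Burgess & Thompson's
construction: project the regional effects onto the leading principal
components of the weight-scaled LD matrix, then run the GLS estimator in
component space.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps

from .io import MRResult

logger = logging.getLogger(__name__)


def _result(method, alpha, se, m, region=None, converged=True) -> MRResult:
    if se is not None and np.isfinite(se) and se > 0:
        p = float(2.0 * sps.norm.sf(abs(alpha) / se))
        p = max(p, np.nextafter(0, 1))
    else:
        p = np.nan
    return MRResult(
        method=method,
        alpha_hat=float(alpha),
        se_alpha=float(se) if se is not None else np.nan,
        p_alpha=p,
        m_snps=int(m),
        region=region,
        converged=converged,
    )


def wald_ratio(bx: float, se_x: float, by: float, se_y: float,
               region=None) -> MRResult:
    """Single-instrument causal estimate ``by / bx``.

    The standard error is the first-order delta approximation ``se_y/|bx|``,
    which ignores the uncertainty of the (genome-wide significant, hence
    precisely estimated) exposure effect.
    """
    if bx == 0:
        return _result("wald_ratio", np.nan, np.nan, 1, region, converged=False)
    return _result("wald_ratio", by / bx, se_y / abs(bx), 1, region)


def mr_ivw(bx, by, se_y, region=None) -> MRResult:
    """Fixed-effect inverse-variance weighted estimate over independent IVs.

    Equivalent to weighted least squares of ``by`` on ``bx`` without
    intercept with weights ``se_y**-2``. Degenerates to the Wald ratio for a
    single instrument.
    """
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    if bx.size == 0:
        return _result("mr_ivw", np.nan, np.nan, 0, region, converged=False)
    w = se_y**-2
    denom = float(np.sum(w * bx * bx))
    if denom <= 0:
        return _result("mr_ivw", np.nan, np.nan, bx.size, region, converged=False)
    alpha = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    return _result("mr_ivw", alpha, se, bx.size, region)


def _gls(bx, by, omega) -> tuple[float, float]:
    oi_bx = np.linalg.solve(omega, bx)
    denom = float(bx @ oi_bx)
    alpha = float(by @ oi_bx) / denom
    return alpha, denom**-0.5


def mr_ivw_ld(bx, by, se_y, C, region=None, _method_tag="mr_ivw_ld") -> MRResult:
    """Generalized IVW accounting for LD between instruments.

    Uses Omega = diag(se_y) C diag(se_y); with C = I this reduces exactly to
    :func:`mr_ivw`. A singular Omega is ridge-repaired by adding escalating
    multiples of the average diagonal (1e-8 up to 1e-4 of trace/m), logged.
    """
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    C = np.asarray(C, dtype=float)
    if bx.size == 0:
        return _result(_method_tag, np.nan, np.nan, 0, region, converged=False)
    omega = C * np.outer(se_y, se_y)
    scale = np.trace(omega) / omega.shape[0]
    ridge = 0.0
    while True:
        try:
            alpha, se = _gls(bx, by, omega + ridge * np.eye(len(bx)))
            if np.isfinite(alpha) and np.isfinite(se):
                break
        except np.linalg.LinAlgError:
            pass
        ridge = 1e-8 * scale if ridge == 0.0 else ridge * 10.0
        if ridge > 1e-4 * scale:
            return _result(_method_tag, np.nan, np.nan, bx.size, region,
                           converged=False)
        logger.warning("%s: singular Omega, ridge repair %e", _method_tag, ridge)
    return _result(_method_tag, alpha, se, bx.size, region)


def mr_pca(bx, by, se_y, C, variance_kept: float = 0.99, region=None) -> MRResult:
    """PCA-MR over all regional SNPs (Burgess & Thompson construction).

    The LD matrix is scaled by the instrument-strength weights
    ``w = bx/se_y`` (W = C * outer(w, w)), decomposed, and the leading
    components retaining ``variance_kept`` of the trace are kept. Effects and
    the outcome covariance are projected onto those components and the GLS
    estimator is applied in the projected space. With full retention this
    equals :func:`mr_ivw_ld` on the original SNPs.
    """
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    C = np.asarray(C, dtype=float)
    w = bx / se_y
    if not np.any(w != 0):
        return _result("mr_pca", np.nan, np.nan, bx.size, region, converged=False)

    W = C * np.outer(w, w)
    lam, V = np.linalg.eigh(W)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    lam = np.clip(lam, 0.0, None)
    if variance_kept >= 1.0:
        k = int((lam > 0).sum()) or 1
    else:
        k = int(np.searchsorted(np.cumsum(lam), variance_kept * lam.sum()) + 1)
    V = V[:, :k]

    bx_p = V.T @ bx
    by_p = V.T @ by
    omega_p = V.T @ (C * np.outer(se_y, se_y)) @ V
    res = mr_ivw_ld(bx_p, by_p, np.ones(k), omega_p, region=region,
                    _method_tag="mr_pca")
    # omega passed directly: se_y placeholder ones, C carries the covariance
    res.m_snps = bx.size
    return res
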