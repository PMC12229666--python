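"""Generative model for exposure/outcome GWAS summary statistics in one region.

The simulator mirrors a cis molecular-QTL study feeding a large outcome
GWAS: per-SNP causal effects are drawn sparse (``m_causal`` SNPs) or
infinitesimal (``m_causal = m``), marginalized through the LD matrix, and
observed with correlated sampling noise:

    betaX = C gammaX + N(0, C (1 - h2x) / nX)
    betaY = C (alpha gammaX + gammaY) + N(0, C (1 - alpha^2 h2x - h2y) / nY)

After drawing, the causal vectors are rescaled so the realized genetic
variances ``gamma' C gamma`` equal ``h2x`` and ``h2y`` exactly, which keeps
the residual-variance terms internally consistent and removes
between-replicate heritability jitter. Imprecise LD references are produced
by forming the sample correlation of ``n_ref`` Gaussian vectors drawn with
covariance C, distributionally equivalent to Wishart-sampling C.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LDMatrix, SummaryStats

logger = logging.getLogger(__name__)


class ScenarioInfeasible(RuntimeError):
    """Raised when causal-set selection cannot satisfy the LD constraints."""


@dataclass
class ScenarioSpec:
    """One simulation parameterization.

    Defaults reproduce the baseline study conditions: an exposure cohort of
    10,000, an outcome cohort of 300,000, a region of 2,068 SNPs, ten causal
    SNPs per trait with unconstrained placement, and an exact LD reference.
    ``n_ref = None`` means the methods receive the true C.
    """

    alpha: float = 0.0
    h2x: float = 0.1
    h2y: float = 1e-20
    m_causal: int = 10
    r_causal_min: float = 0.0
    r_causal_max: float = 1.0
    n_ref: int | None = None
    nX: int = 10_000
    nY: int = 300_000
    m: int = 2068
    seed: int = 0
    replicates: int = 1000

    def __post_init__(self):
        if not 0 <= self.h2x < 1 or not 0 <= self.h2y < 1:
            raise ValueError("heritabilities must lie in [0, 1)")
        if 1.0 - self.alpha**2 * self.h2x - self.h2y <= 0:
            raise ValueError("outcome residual variance is not positive")
        if self.m_causal > self.m:
            raise ValueError("m_causal cannot exceed m")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        n_ref = d.get("n_ref")
        if isinstance(n_ref, str):
            d = dict(d)
            d["n_ref"] = None if n_ref.lower() in ("exact", "inf", "infinite") else int(n_ref)
        return cls(**d)


def synth_ld(
    m: int,
    block_size: int = 50,
    rho: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> LDMatrix:
    """Synthetic haplotype-block LD: block-diagonal AR(1) correlation.

    Blocks have Poisson-distributed lengths around ``block_size``; within a
    block, correlation decays as ``r**|i-j|`` with a per-block decay drawn
    from U(0.5 rho, rho). Allele orientations are randomized by symmetric
    sign flips, which preserves positive semidefiniteness and the unit
    diagonal. Deterministic given the seed.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    C = np.zeros((m, m))
    start = 0
    while start < m:
        size = min(max(2, int(rng.poisson(block_size))), m - start)
        r = rng.uniform(0.5 * rho, rho) if rho > 0 else 0.0
        idx = np.arange(size)
        C[start:start + size, start:start + size] = r ** np.abs(
            idx[:, None] - idx[None, :]
        )
        start += size
    signs = rng.choice([-1.0, 1.0], size=m)
    C *= np.outer(signs, signs)
    np.fill_diagonal(C, 1.0)

    variants = pd.DataFrame(
        {
            "chrom": np.repeat("1", m),
            "pos": 1_000_000 + 1000 * np.arange(m, dtype=np.int64),
            "a1": rng.choice(["A", "C"], size=m),
            "a2": rng.choice(["G", "T"], size=m),
            "maf": rng.uniform(0.05, 0.5, size=m),
        }
    )
    return LDMatrix(C, variants, n_ref=None)


def select_causal_sets(
    C: LDMatrix | np.ndarray,
    m_causal: int,
    r_min: float = 0.0,
    r_max: float = 1.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick exposure and outcome causal SNP index sets under LD constraints.

    With the unconstrained window (0, 1) both sets are uniform random draws.
    Otherwise the exposure set grows iteratively: each new SNP must have
    ``r_min <= |r| <= r_max`` against every previously selected SNP; the
    outcome set is drawn from SNPs within that LD window of at least one
    exposure causal SNP. Raises :class:`ScenarioInfeasible` after bounded
    retries, mirroring scenarios that fail to complete.
    """
    Cm = C.C if isinstance(C, LDMatrix) else np.asarray(C)
    m = Cm.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if r_min <= 0.0 and r_max >= 1.0:
        return (
            np.sort(rng.choice(m, size=m_causal, replace=False)),
            np.sort(rng.choice(m, size=m_causal, replace=False)),
        )

    absC = np.abs(Cm)
    for _ in range(max_tries):
        exposure = [int(rng.integers(m))]
        ok = True
        while len(exposure) < m_causal:
            mask = np.ones(m, dtype=bool)
            mask[exposure] = False
            for s in exposure:
                mask &= (absC[s] >= r_min) & (absC[s] <= r_max)
            candidates = np.nonzero(mask)[0]
            if candidates.size == 0:
                ok = False
                break
            exposure.append(int(rng.choice(candidates)))
        if not ok:
            continue
        window = np.zeros(m, dtype=bool)
        for s in exposure:
            window |= (absC[s] >= r_min) & (absC[s] <= r_max)
        window[exposure] = True  # causal SNPs may coincide across traits
        candidates = np.nonzero(window)[0]
        if candidates.size < m_causal:
            continue
        outcome = np.sort(rng.choice(candidates, size=m_causal, replace=False))
        return np.sort(np.array(exposure)), outcome
    raise ScenarioInfeasible(
        f"no causal sets satisfying |r| in [{r_min}, {r_max}] after {max_tries} tries"
    )


def _scaled_sparse_effects(m, causal_idx, h2, Cm, rng) -> np.ndarray:
    gamma = np.zeros(m)
    gamma[causal_idx] = rng.normal(size=len(causal_idx))
    realized = float(gamma @ Cm @ gamma)
    if realized <= 0:
        # pathological draw (all zero); retry recursively
        return _scaled_sparse_effects(m, causal_idx, h2, Cm, rng)
    gamma *= np.sqrt(h2 / realized)
    return gamma


def simulate_summary_stats(
    C: LDMatrix | np.ndarray,
    spec: ScenarioSpec,
    causal_sets: tuple[np.ndarray, np.ndarray],
    seed: int | np.random.Generator = 0,
    chol: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one replicate of marginal effect vectors (betaX, betaY).

    ``chol`` may carry a precomputed Cholesky factor of C (plus jitter) so
    that benchmark loops amortize the factorization. Standard errors of the
    standardized effects are deterministic at ``1/sqrt(n)``; see
    :func:`theoretical_se`.
    """
    Cm = C.C if isinstance(C, LDMatrix) else np.asarray(C)
    m = Cm.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if chol is None:
        chol = cholesky_with_jitter(Cm)
    cX, cY = causal_sets

    gammaX = _scaled_sparse_effects(m, cX, spec.h2x, Cm, rng)
    gammaY = _scaled_sparse_effects(m, cY, spec.h2y, Cm, rng)

    noiseX = chol @ rng.normal(size=m) * np.sqrt((1.0 - spec.h2x) / spec.nX)
    var_y = 1.0 - spec.alpha**2 * spec.h2x - spec.h2y
    noiseY = chol @ rng.normal(size=m) * np.sqrt(var_y / spec.nY)

    betaX = Cm @ gammaX + noiseX
    betaY = Cm @ (spec.alpha * gammaX + gammaY) + noiseY
    return betaX, betaY


def theoretical_se(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Standard errors of standardized effects at the simulated sample sizes."""
    return (
        np.full(spec.m, spec.nX**-0.5),
        np.full(spec.m, spec.nY**-0.5),
    )


def cholesky_with_jitter(Cm: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Cholesky factor of C, adding escalating diagonal jitter if needed."""
    for _ in range(8):
        try:
            return np.linalg.cholesky(Cm + jitter * np.eye(Cm.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError("correlation matrix could not be factorized")


def sample_reference_ld(
    C: LDMatrix,
    n_ref: int | None,
    seed: int | np.random.Generator = 0,
    max_regularization: float = 0.5,
) -> LDMatrix:
    """Imprecisely measured LD through Wishart-type sampling of C.

    Draws ``n_ref`` latent Gaussian vectors with covariance C and returns
    their sample correlation matrix — equal in distribution to normalizing a
    Wishart(n_ref, C/n_ref) draw, and valid also for n_ref < m. If C is not
    positive semidefinite, escalating constants (up to
    ``max_regularization``) are added to the diagonal before factorization.
    ``n_ref = None`` (exact reference) returns C unchanged.
    """
    if n_ref is None:
        return C
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Cm = C.C
    m = Cm.shape[0]
    reg = 0.0
    while True:
        try:
            L = np.linalg.cholesky(Cm + reg * np.eye(m))
            break
        except np.linalg.LinAlgError:
            reg = 1e-6 if reg == 0.0 else reg * 10.0
            if reg > max_regularization:
                raise np.linalg.LinAlgError(
                    f"LD matrix not PSD even after +{max_regularization} "
                    "diagonal regularization"
                )
            logger.warning("sample_reference_ld: diagonal regularization %e", reg)
    G = rng.normal(size=(int(n_ref), m)) @ L.T
    S = np.corrcoef(G, rowvar=False)
    np.fill_diagonal(S, 1.0)
    return LDMatrix(np.clip(S, -1.0, 1.0), C.variants, n_ref=int(n_ref))


# ---------------------------------------------------------------------------
# replicate-level convenience


@dataclass
class RegionSimulator:
    """Amortizes the per-region factorizations across many replicates."""

    ld: LDMatrix
    spec: ScenarioSpec
    chol: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.ld.m != self.spec.m:
            raise ValueError("LD matrix size does not match scenario m")
        self.chol = cholesky_with_jitter(self.ld.C)

    def replicate(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        causal = select_causal_sets(
            self.ld,
            self.spec.m_causal,
            self.spec.r_causal_min,
            self.spec.r_causal_max,
            seed=rng,
        )
        return simulate_summary_stats(
            self.ld, self.spec, causal, seed=rng, chol=self.chol
        )

    def to_summary_stats(
        self, betaX: np.ndarray, betaY: np.ndarray
    ) -> tuple[SummaryStats, SummaryStats]:
        """Package one replicate as two SummaryStats tables (for pipeline IO)."""
        from scipy import stats as sps

        seX, seY = theoretical_se(self.spec)
        v = self.ld.variants
        out = []
        for beta, se, n in ((betaX, seX, self.spec.nX), (betaY, seY, self.spec.nY)):
            z = beta / se
            out.append(
                SummaryStats(
                    chrom=v["chrom"].to_numpy(dtype=object),
                    pos=v["pos"].to_numpy(),
                    a1=v["a1"].to_numpy(dtype=object),
                    a2=v["a2"].to_numpy(dtype=object),
                    beta=beta,
                    se=se,
                    z=z,
                    n=np.full(self.spec.m, float(n)),
                    p=np.clip(2.0 * sps.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0),
                )
            )
        return out[0], out[1]
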