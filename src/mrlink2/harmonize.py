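"""Allele alignment, QC filtering and effect standardization.

Harmonization brings an exposure study, an outcome study and an LD reference
onto one variant set with a shared effect allele, then converts both studies
to standardized effects ``beta = z / sqrt(n + z^2)`` with standard error
``1 / sqrt(n + z^2)`` so that effect magnitudes are comparable between
studies of different sample size and phenotype scale.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps

from .io import LDMatrix, SummaryStats

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def standardize_effects(z, n):
    """Standardized effect and standard error from Z-scores and sample sizes.

    Returns ``(beta, se)`` with ``beta = z/sqrt(n+z^2)``, ``se = 1/sqrt(n+z^2)``.
    ``n`` must be positive.
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    denom = np.sqrt(n + z * z)
    return z / denom, 1.0 / denom


def is_palindromic(a1, a2) -> np.ndarray:
    """A/T and C/G SNPs, whose strand cannot be resolved from alleles alone."""
    a1 = np.asarray(a1, dtype=object)
    a2 = np.asarray(a2, dtype=object)
    return np.array([_COMPLEMENT[x] == y for x, y in zip(a1, a2)])


def _align_to_reference(stats: SummaryStats, ref: LDMatrix):
    """Match variants on (chrom, pos, alleles) and flip signs where a1/a2 swap.

    Returns (stats_row_index, ref_row_index, sign) for the matched records.
    """
    ref_idx = {}
    for j, key in enumerate(ref.keys()):
        ref_idx[(key.chrom, key.pos, key.a1, key.a2)] = (j, 1.0)
        ref_idx[(key.chrom, key.pos, key.a2, key.a1)] = (j, -1.0)
    rows, cols, signs = [], [], []
    for i, (c, p, x1, x2) in enumerate(
        zip(stats.chrom, stats.pos, stats.a1, stats.a2)
    ):
        hit = ref_idx.get((str(c), int(p), x1, x2))
        if hit is not None:
            rows.append(i)
            cols.append(hit[0])
            signs.append(hit[1])
    return np.array(rows, dtype=int), np.array(cols, dtype=int), np.array(signs)


def _oriented(stats: SummaryStats, rows, cols, signs, ref: LDMatrix) -> SummaryStats:
    """Subset to matched rows and re-express effects on the reference a1."""
    out = stats.take(rows)
    out.z = out.z * signs
    out.beta = out.beta * signs
    v = ref.variants.iloc[cols]
    out.chrom = v["chrom"].to_numpy(dtype=object)
    out.pos = v["pos"].to_numpy(dtype=np.int64)
    out.a1 = v["a1"].to_numpy(dtype=object)
    out.a2 = v["a2"].to_numpy(dtype=object)
    return out


def harmonize_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    reference: LDMatrix,
    maf_threshold: float = 0.005,
    completeness: float = 0.95,
    keep_palindromic: bool = False,
) -> tuple[SummaryStats, SummaryStats, LDMatrix]:
    """Restrict to the three-way variant intersection and standardize effects.

    Pipeline: intersect on (chrom, pos, alleles) with sign flips for swapped
    a1/a2 -> remove palindromic SNPs -> drop reference MAF < ``maf_threshold``
    -> drop variants measured in < ``completeness`` x max(n) per trait (when
    per-variant n varies) -> standardize via the z/sqrt(n+z^2) transform.
    Raises ``ValueError`` naming the stage that emptied the variant set.
    """
    er, ec, es = _align_to_reference(exposure, reference)
    or_, oc, os_ = _align_to_reference(outcome, reference)
    if len(er) == 0 or len(or_) == 0:
        raise ValueError("harmonization failed: no variants shared with LD reference")

    shared, e_in, o_in = np.intersect1d(ec, oc, return_indices=True)
    if shared.size == 0:
        raise ValueError("harmonization failed: exposure/outcome share no variants")
    er, es = er[e_in], es[e_in]
    or_, os_ = or_[o_in], os_[o_in]
    ref_cols = shared
    logger.info("harmonize: %d variants in three-way intersection", ref_cols.size)

    v = reference.variants.iloc[ref_cols]
    keep = np.ones(ref_cols.size, dtype=bool)
    if not keep_palindromic:
        keep &= ~is_palindromic(v["a1"].to_numpy(), v["a2"].to_numpy())
        if not keep.any():
            raise ValueError("harmonization failed: all variants palindromic")
    maf = reference.maf
    if maf is not None:
        keep &= maf[ref_cols] >= maf_threshold
        if not keep.any():
            raise ValueError("harmonization failed: MAF filter removed all variants")

    er, es, or_, os_, ref_cols = (
        er[keep], es[keep], or_[keep], os_[keep], ref_cols[keep],
    )

    # per-trait sample-size completeness, only meaningful when n varies
    for rows_ref, stats_ in ((er, exposure), (or_, outcome)):
        n = stats_.n[rows_ref]
        if np.isfinite(n).all() and np.unique(n).size > 1:
            ok = n >= completeness * np.max(n)
            er, es, or_, os_, ref_cols = (
                er[ok], es[ok], or_[ok], os_[ok], ref_cols[ok],
            )
    if ref_cols.size == 0:
        raise ValueError("harmonization failed: sample-size filter removed all variants")

    exp_out = _oriented(exposure, er, ref_cols, es, reference)
    out_out = _oriented(outcome, or_, ref_cols, os_, reference)
    for s in (exp_out, out_out):
        s.beta, s.se = standardize_effects(s.z, s.n)
        s.p = np.clip(2.0 * sps.norm.sf(np.abs(s.z)), np.nextafter(0, 1), 1.0)

    order = np.argsort(ref_cols)
    return (
        exp_out.take(order),
        out_out.take(order),
        reference.submatrix(ref_cols[order]),
    )
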