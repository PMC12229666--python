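"""P-value clumping, region merging and instrument selection.

The clumping algorithm mirrors PLINK's ``--clump`` semantics: greedily take
the smallest-P variant with ``p <= p_thresh`` as an index, absorb every
unassigned variant within ``window_kb`` of it whose squared correlation with
it is at least ``r2_thresh``, repeat until no eligible index remains. Index
variants then spawn symmetric windows that are unioned into associated
regions, which can therefore grow well beyond a single window.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LDMatrix, SummaryStats


@dataclass
class Clump:
    index: int                      # row of the index variant
    members: list[int] = field(default_factory=list)  # rows incl. the index


@dataclass
class Region:
    chrom: str
    start: int                      # 1-based inclusive
    end: int                        # 1-based inclusive
    members: list[int] = field(default_factory=list)  # clump-index rows inside


def clump(
    stats: SummaryStats,
    ld: LDMatrix,
    window_kb: float = 250.0,
    r2_thresh: float = 0.01,
    p_thresh: float = 5e-8,
) -> list[Clump]:
    """Greedy P-value clumping of ``stats`` against ``ld``.

    ``stats`` and ``ld`` must be row-aligned on the same variant set. Ties in
    P are broken by smaller genomic position. Returns an empty list when no
    variant reaches ``p_thresh``.
    """
    if len(stats) != ld.m:
        raise ValueError("stats and LD matrix are not aligned")
    p = stats.p
    pos = stats.pos
    chrom = stats.chrom
    r2 = ld.C**2
    window = float(window_kb) * 1000.0  # inf disables the distance constraint

    unassigned = np.ones(len(stats), dtype=bool)
    clumps: list[Clump] = []
    order = np.lexsort((pos, p))  # smallest P first, then position
    for i in order:
        if not unassigned[i] or p[i] > p_thresh:
            continue
        near = (
            unassigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
            & (r2[i] >= r2_thresh)
        )
        near[i] = True
        members = np.nonzero(near)[0]
        unassigned[members] = False
        clumps.append(Clump(index=int(i), members=[int(j) for j in members]))
    return clumps


def regions_from_clumps(
    stats: SummaryStats, clumps: list[Clump], window_kb: float = 250.0
) -> list[Region]:
    """Union of per-index windows, merged whenever intervals touch or overlap."""
    window = int(window_kb * 1000)
    intervals = sorted(
        (
            str(stats.chrom[c.index]),
            int(stats.pos[c.index]) - window,
            int(stats.pos[c.index]) + window,
            c.index,
        )
        for c in clumps
    )
    regions: list[Region] = []
    for chrom, start, end, idx in intervals:
        start = max(start, 1)
        if regions and regions[-1].chrom == chrom and start <= regions[-1].end + 1:
            regions[-1].end = max(regions[-1].end, end)
            regions[-1].members.append(idx)
        else:
            regions.append(Region(chrom=chrom, start=start, end=end, members=[idx]))
    return regions


def variants_in_region(stats: SummaryStats, region: Region) -> np.ndarray:
    """Row indices of all variants lying inside a region."""
    return np.nonzero(
        (stats.chrom == region.chrom)
        & (stats.pos >= region.start)
        & (stats.pos <= region.end)
    )[0]


def select_instruments(
    stats: SummaryStats,
    ld: LDMatrix,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.01,
) -> np.ndarray:
    """Mutually independent instruments: the clump index variants.

    Every returned pair has squared correlation below ``r2_thresh`` and every
    instrument has ``p <= p_thresh``. The distance window is disabled
    (regions are already distance-bounded).
    """
    clumps_ = clump(stats, ld, window_kb=np.inf, r2_thresh=r2_thresh, p_thresh=p_thresh)
    return np.array(sorted(c.index for c in clumps_), dtype=int)


def regions_to_bed(regions: list[Region]) -> str:
    """BED export: 0-based half-open, tab-separated, one region per line."""
    return "\n".join(f"{r.chrom}\t{r.start - 1}\t{r.end}" for r in regions)
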