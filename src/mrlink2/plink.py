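"""Minimal PLINK-1 binary (.bed/.bim/.fam) reader and writer.

Only SNP-major hard-call data are supported, which is what LD reference
panels ship as. The 2-bit codes are, per byte and from the lowest bit pair:
``00`` homozygous A1, ``01`` missing, ``10`` heterozygous, ``11`` homozygous
A2. Dosages count copies of the A1 allele (.bim column 5).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypePanel

_MAGIC = bytes((0x6C, 0x1B))
_SNP_MAJOR = 0x01

# code -> A1-allele dosage
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])

_BIM_COLUMNS = ["chrom", "rsid", "cm", "pos", "a1", "a2"]


def read_genotype_panel(bed_prefix) -> GenotypePanel:
    """Read a ``.bed/.bim/.fam`` triplet into a :class:`GenotypePanel`."""
    prefix = Path(bed_prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None, names=_BIM_COLUMNS,
        dtype={"chrom": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    samples = [f"{f}_{i}" for f, i in zip(fam[0], fam[1])]
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:2].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not a PLINK-1 .bed file)")
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#x})")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * m:
        raise ValueError(
            f"{prefix}.bed: {body.size} data bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants"
        )

    codes = body.reshape(m, bytes_per_variant)
    # unpack the four 2-bit genotypes of each byte, sample-ordered
    expanded = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        expanded[:, k::4] = (codes >> (2 * k)) & 0b11
    dosages = _DECODE[expanded[:, :n]].T  # samples x variants

    variants = bim[["chrom", "pos", "a1", "a2"]].copy()
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


def write_genotype_panel(panel: GenotypePanel, bed_prefix) -> None:
    """Write a :class:`GenotypePanel` as a SNP-major ``.bed/.bim/.fam`` triplet."""
    prefix = Path(bed_prefix)
    n, m = panel.dosages.shape

    bim = panel.variants.copy()
    bim.insert(1, "rsid", [
        f"{c}:{p}" for c, p in zip(bim["chrom"], bim["pos"])
    ])
    bim.insert(2, "cm", 0)
    bim[["chrom", "rsid", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    samples = panel.samples or [f"fam{i}_{i}" for i in range(n)]
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, s in enumerate(samples):
            fid, _, iid = s.partition("_")
            fh.write(f"{fid or i} {iid or i} 0 0 0 -9\n")

    encode = {2.0: 0, 1.0: 2, 0.0: 3}  # dosage -> 2-bit code; NaN -> 1
    bytes_per_variant = (n + 3) // 4
    body = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for j in range(m):
        for i in range(n):
            d = panel.dosages[i, j]
            code = 1 if np.isnan(d) else encode[float(d)]
            body[j, i // 4] |= code << (2 * (i % 4))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + bytes((_SNP_MAJOR,)))
        fh.write(body.tobytes())
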