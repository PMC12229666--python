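"""Domain containers and readers/writers for summary statistics and LD.

The canonical on-disk format for summary statistics is a tab-separated table
with a header; column names are resolved through a user-supplied mapping so
that files from different GWAS pipelines can be ingested without rewriting.
Effects are stored on the standardized scale (trait standard deviations per
allele standard deviation) once harmonized; raw files may carry either
``z`` + ``n`` or ``beta`` + ``se``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")

#: canonical column order for summary-statistic tables
SUMSTAT_COLUMNS = ["chrom", "pos", "a1", "a2", "beta", "se", "z", "n", "p"]


class VariantKey(NamedTuple):
    """Identity of a biallelic SNP: chromosome, 1-based position and alleles.

    ``a1`` is the effect allele, ``a2`` the other allele. Alleles are single
    uppercase nucleotides; multi-allelic and indel records are rejected by
    the readers before a key is ever built.
    """

    chrom: str
    pos: int
    a1: str
    a2: str

    @property
    def unordered_alleles(self) -> frozenset:
        return frozenset((self.a1, self.a2))


def _as_str_array(values) -> np.ndarray:
    return np.asarray(values, dtype=object)


@dataclass
class SummaryStats:
    """Per-variant marginal association records for one trait.

    All arrays share one length. ``beta``/``se`` are standardized effects and
    their standard errors, ``z`` the association Z-score, ``n`` the
    per-variant sample size, ``p`` the two-sided P value.
    """

    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    n: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.a1 = _as_str_array(self.a1)
        self.a2 = _as_str_array(self.a2)
        for name in ("beta", "se", "z", "n", "p"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(getattr(self, c)) for c in SUMSTAT_COLUMNS}
        if len(lengths) != 1:
            raise ValueError("SummaryStats arrays must share one length")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), x1, x2)
            for c, p, x1, x2 in zip(self.chrom, self.pos, self.a1, self.a2)
        ]

    def take(self, idx) -> "SummaryStats":
        idx = np.asarray(idx)
        return SummaryStats(**{c: getattr(self, c)[idx] for c in SUMSTAT_COLUMNS})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in SUMSTAT_COLUMNS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryStats":
        return cls(**{c: df[c].to_numpy() for c in SUMSTAT_COLUMNS})


@dataclass
class GenotypePanel:
    """Hard-call allele dosages for a reference cohort.

    ``dosages`` is a samples x variants float matrix counting copies of the
    effect allele (0/1/2), with NaN marking missing genotypes.
    """

    dosages: np.ndarray
    variants: pd.DataFrame  # columns chrom, pos, a1, a2
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be hard calls in {0,1,2} or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class LDMatrix:
    """SNP x SNP Pearson correlation matrix with variant metadata.

    ``n_ref`` is the reference-panel sample count; ``None`` marks an exact
    (noise-free) matrix, as used in simulations with perfectly measured LD.
    ``variants`` carries chrom/pos/a1/a2 and, when known, a ``maf`` column.
    """

    C: np.ndarray
    variants: pd.DataFrame
    n_ref: int | None = None

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        m = self.C.shape[0]
        if self.C.shape != (m, m):
            raise ValueError("C must be square")
        if len(self.variants) != m:
            raise ValueError("variant metadata does not match C")
        if not np.allclose(self.C, self.C.T, atol=1e-8):
            raise ValueError("C must be symmetric")
        if not np.allclose(np.diag(self.C), 1.0, atol=1e-6):
            raise ValueError("C must have a unit diagonal")
        if np.nanmax(np.abs(self.C)) > 1.0 + 1e-6:
            raise ValueError("correlations must lie in [-1, 1]")
        self.C = 0.5 * (self.C + self.C.T)
        np.fill_diagonal(self.C, 1.0)
        self.variants = self.variants.reset_index(drop=True)

    @property
    def m(self) -> int:
        return self.C.shape[0]

    @property
    def maf(self) -> np.ndarray | None:
        if "maf" in self.variants.columns:
            return self.variants["maf"].to_numpy(dtype=float)
        return None

    def keys(self) -> list[VariantKey]:
        v = self.variants
        return [
            VariantKey(str(c), int(p), str(x1), str(x2))
            for c, p, x1, x2 in zip(v["chrom"], v["pos"], v["a1"], v["a2"])
        ]

    def submatrix(self, idx) -> "LDMatrix":
        idx = np.asarray(idx)
        return LDMatrix(
            self.C[np.ix_(idx, idx)], self.variants.iloc[idx], n_ref=self.n_ref
        )


@dataclass
class MRResult:
    """One causal-effect estimate for an (exposure, outcome, region) triple."""

    method: str
    alpha_hat: float
    se_alpha: float
    p_alpha: float
    h2x_hat: float | None = None
    h2y_hat: float | None = None
    p_h2y: float | None = None
    m_snps: int = 0
    region: tuple[str, int, int] | None = None
    converged: bool = True

    def to_dict(self) -> dict:
        chrom, start, end = self.region if self.region else (None, None, None)
        return {
            "method": self.method,
            "alpha": self.alpha_hat,
            "se_alpha": self.se_alpha,
            "p_alpha": self.p_alpha,
            "h2x": self.h2x_hat,
            "h2y": self.h2y_hat,
            "p_h2y": self.p_h2y,
            "m_snps": self.m_snps,
            "chrom": chrom,
            "start": start,
            "end": end,
            "converged": self.converged,
        }


def write_results(results: Sequence[MRResult], path) -> None:
    """Write one row per (region, method) as a tab-separated table."""
    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary-statistic IO


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    max_n: float | None = None,
) -> SummaryStats:
    """Read a tab-separated summary-statistic file.

    ``column_map`` maps canonical names (chrom, pos, a1, a2, z, beta, se, n,
    p) to the file's header names; canonical names present in the header are
    picked up without mapping. Either ``z`` or ``beta``+``se`` must resolve.
    Records with invalid alleles, non-positive se/n or p outside (0, 1] are
    dropped with a logged count. When ``n`` is absent, the study-level
    maximum sample size ``max_n`` is imputed for every variant.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.empty:
        raise ValueError(f"summary-statistic file {path} is empty")
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)

    for required in ("chrom", "pos", "a1", "a2"):
        if required not in df.columns:
            raise ValueError(f"cannot resolve required column {required!r} in {path}")
    has_z = "z" in df.columns
    has_beta = "beta" in df.columns and "se" in df.columns
    if not has_z and not has_beta:
        raise ValueError(f"need either z or beta+se columns in {path}")

    n_in = len(df)
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    ok = (
        df["a1"].isin(_NUCLEOTIDES)
        & df["a2"].isin(_NUCLEOTIDES)
        & (df["a1"] != df["a2"])
    )
    if has_beta:
        ok &= pd.to_numeric(df["se"], errors="coerce") > 0
    if "p" in df.columns:
        pvals = pd.to_numeric(df["p"], errors="coerce")
        ok &= (pvals > 0) & (pvals <= 1)
    df = df[ok].copy()
    dropped = n_in - len(df)
    if dropped:
        logger.info("read_summary_stats: dropped %d invalid records", dropped)
    if df.empty:
        raise ValueError(f"no usable records in {path}")

    # duplicate variant keys: keep first occurrence
    dup = df.duplicated(subset=["chrom", "pos", "a1", "a2"])
    if dup.any():
        logger.info("read_summary_stats: dropped %d duplicate records", int(dup.sum()))
        df = df[~dup]

    beta = pd.to_numeric(df["beta"], errors="coerce") if has_beta else None
    se = pd.to_numeric(df["se"], errors="coerce") if has_beta else None
    if has_z:
        z = pd.to_numeric(df["z"], errors="coerce").to_numpy(dtype=float)
    else:
        z = (beta / se).to_numpy(dtype=float)
    if not has_beta:
        beta = pd.Series(np.full(len(df), np.nan))
        se = pd.Series(np.full(len(df), np.nan))

    if "n" in df.columns:
        n = pd.to_numeric(df["n"], errors="coerce").to_numpy(dtype=float)
    else:
        if max_n is None:
            raise ValueError(
                f"{path} has no per-variant n; pass max_n (study maximum sample size)"
            )
        n = np.full(len(df), float(max_n))

    if "p" in df.columns:
        p = pd.to_numeric(df["p"], errors="coerce").to_numpy(dtype=float)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.nextafter(0, 1), 1.0)

    return SummaryStats(
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        a1=df["a1"].to_numpy(dtype=object),
        a2=df["a2"].to_numpy(dtype=object),
        beta=beta.to_numpy(dtype=float),
        se=se.to_numpy(dtype=float),
        z=z,
        n=n,
        p=p,
    )


def write_summary_stats(stats_: SummaryStats, path) -> None:
    """Write canonical tab-separated summary statistics (full precision)."""
    stats_.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# LD


def compute_ld(
    panel: GenotypePanel, variant_idx: Sequence[int] | None = None
) -> LDMatrix:
    """Pairwise Pearson correlation of mean-imputed, standardized dosages.

    Monomorphic variants (zero dosage variance after imputation) are excluded
    with a warning since their correlation is undefined. The minor-allele
    frequency of each retained variant is computed from the panel and stored
    in the variant metadata; ``n_ref`` is the panel's sample count.
    """
    if variant_idx is None:
        variant_idx = np.arange(panel.n_variants)
    variant_idx = np.asarray(variant_idx)
    X = panel.dosages[:, variant_idx].copy()
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples to compute LD")

    col_mean = np.nanmean(X, axis=0)
    missing = np.isnan(X)
    X[missing] = np.take(col_mean, np.nonzero(missing)[1])

    sd = X.std(axis=0)
    poly = sd > 0
    if not poly.all():
        logger.warning("compute_ld: excluded %d monomorphic variants", int((~poly).sum()))
    X = X[:, poly]
    variant_idx = variant_idx[poly]

    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    C = (Z.T @ Z) / n
    np.fill_diagonal(C, 1.0)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)

    freq = col_mean[poly] / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    variants = panel.variants.iloc[variant_idx].reset_index(drop=True).copy()
    variants["maf"] = maf
    return LDMatrix(C, variants, n_ref=n)


def read_ld_matrix(matrix_path, variants_path) -> LDMatrix:
    """Read a dense LD matrix (TSV, no header) with a variant sidecar TSV.

    The sidecar must carry chrom/pos/a1/a2 and may carry maf and n_ref
    columns; n_ref, if present, must be constant.
    """
    C = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    n_ref = None
    if "n_ref" in variants.columns:
        vals = variants["n_ref"].unique()
        if len(vals) != 1:
            raise ValueError("n_ref column must be constant")
        n_ref = int(vals[0])
        variants = variants.drop(columns=["n_ref"])
    return LDMatrix(C, variants, n_ref=n_ref)


def write_ld_matrix(ld: LDMatrix, matrix_path, variants_path) -> None:
    np.savetxt(matrix_path, ld.C, delimiter="\t", fmt="%.17g")
    out = ld.variants.copy()
    if ld.n_ref is not None:
        out["n_ref"] = ld.n_ref
    out.to_csv(variants_path, sep="\t", index=False)
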