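import numpy as np
import pandas as pd
import pytest

from mrlink2.io import LDMatrix, SummaryStats


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def random_correlation(m, rng):
    """A well-conditioned random correlation matrix."""
    A = rng.normal(size=(m, m + 5))
    C = A @ A.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def make_variants(m, chrom="1", start=1_000_000, spacing=1000, maf=None, rng=None):
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    a1, a2 = zip(*(alleles[i % 4] for i in range(m)))
    df = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": start + spacing * np.arange(m, dtype=np.int64),
            "a1": a1,
            "a2": a2,
        }
    )
    if maf is not None:
        df["maf"] = maf
    elif rng is not None:
        df["maf"] = rng.uniform(0.05, 0.5, size=m)
    return df


def make_sumstats(variants, z, n, rng=None):
    from scipy import stats as sps

    z = np.asarray(z, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), z.shape)
    se = 1.0 / np.sqrt(n)
    return SummaryStats(
        chrom=variants["chrom"].to_numpy(dtype=object, copy=True),
        pos=variants["pos"].to_numpy(copy=True),
        a1=variants["a1"].to_numpy(dtype=object, copy=True),
        a2=variants["a2"].to_numpy(dtype=object, copy=True),
        beta=z * se,
        se=se,
        z=z,
        n=n,
        p=np.clip(2 * sps.norm.sf(np.abs(z)), 1e-300, 1.0),
    )


@pytest.fixture
def small_ld(rng):
    m = 8
    C = random_correlation(m, rng)
    return LDMatrix(C, make_variants(m, rng=rng))
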