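# mrlink2 — pleiotropy-robust *cis* Mendelian randomization

`mrlink2` estimates whether a molecular exposure (a metabolite level, a
gene's expression, a protein) causally affects an outcome trait, using only
GWAS **summary statistics** from a single associated genomic region plus a
reference **LD matrix**. Classical *cis*-MR estimators (Wald ratio, IVW and
its LD-aware variants) assume instruments act on the outcome only through
the exposure; in a single region that exclusion restriction is routinely
violated by LD-linked horizontal pleiotropy. This package implements a
likelihood that models the pleiotropy explicitly and tests it, together
with the classic estimators, a regional summary-statistic simulator for
benchmarking, and inverse-variance meta-analysis across regions.

## The model

For a region of *m* SNPs with LD matrix **C**, per-SNP effects on the
exposure and outcome are random (infinitesimal architecture):

    gamma_X ~ N(0, sigma2_X),   gamma_Y ~ N(0, sigma2_Y)

with h2_X = m sigma2_X the exposure *cis* heritability and
h2_Y = m sigma2_Y the horizontal-pleiotropy variance. The observed marginal
effects are

    betahat_X = C gamma_X + eta_X
    betahat_Y = C (alpha gamma_X + gamma_Y) + eta_Y

with sampling noise eta ~ N(0, C/n). Integrating out the gammas, the
stacked effects are jointly Gaussian; in the eigenbasis of
C = U L U^T (truncated to the components carrying 99% of the trace) the
2m-dimensional density factorizes into independent bivariate Gaussians, one
per eigenvalue — evaluation is O(m) per likelihood call. Three parameters
(alpha, sigma2_X, sigma2_Y) are fitted by Nelder–Mead; the causal effect
alpha and the pleiotropic variance sigma2_Y are each tested by a
likelihood-ratio test with one degree of freedom.

## A worked example

```python
import numpy as np
from mrlink2 import ScenarioSpec, RegionSimulator, synth_ld, run_mr_link2

spec = ScenarioSpec(alpha=0.15, h2x=0.1, h2y=1e-4, m=300, m_causal=10)
ld = synth_ld(spec.m, seed=1)                       # haplotype-block LD
sim = RegionSimulator(ld=ld, spec=spec)
betaX, betaY = sim.replicate(np.random.default_rng(2))
res = run_mr_link2(betaX, betaY, ld, spec.nX, spec.nY)
print(res.alpha_hat, res.p_alpha, res.h2y_hat, res.p_h2y)
```

Running `python examples/01_single_region_fit.py` (which wraps the above
and adds the competitor estimators) prints:

```
true alpha = 0.15, true h2y = 0.0001
mr_link2 : alpha=+0.155 (se 0.009, p=1.25e-38)  h2y=1.05e-04 (p=2.56e-01)
mr_ivw   : alpha=+0.150 (se 0.006, p=4.62e-124)
mr_ivw_ld: alpha=+0.150 (se 0.006, p=2.72e-123)
mr_pca   : alpha=+0.132 (se 0.005, p=9.35e-137)
```

The likelihood recovers the simulated causal effect (0.15) and estimates
the simulated pleiotropic variance (1e-4) on the right scale; the IVW
family agrees here because the simulated pleiotropy is mild. The other
scripts in `examples/` demonstrate null calibration, the file-based
pipeline, and multi-region meta-analysis with Cochran's Q.

## Command line

```bash
mrlink2 run --exposure X.tsv --outcome Y.tsv \
            --ld-matrix C.tsv --ld-variants C.vars.tsv --out results.tsv
mrlink2 simulate  --scenario scenario.yaml --out sims/
mrlink2 benchmark --scenario scenario.yaml --out bench.tsv
mrlink2 meta      --results results.tsv --out meta.tsv
```

`run` harmonizes the two studies against the LD reference (allele
alignment, palindromic-SNP removal, MAF >= 0.5%, 95% sample-size
completeness, standardization to z/sqrt(n+z^2)), finds associated regions
by P-value clumping (250 kb window, r^2 0.01, P 5e-8, overlapping regions
merged), and writes one result row per region per method plus a JSON
manifest of thresholds and per-stage record counts. An LD reference can
also be a PLINK-1 `.bed/.bim/.fam` panel (`--ld-bed prefix`).

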