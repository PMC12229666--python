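# Methods

## Model and likelihood

One genomic region of *m* biallelic SNPs with population LD (Pearson
correlation) matrix **C**. Genotypes are standardized, traits are
standardized, and all effects are on the standardized scale. The structural
model is

    X = G gamma_X + eps_X
    Y = alpha X + G gamma_Y + eps_Y

with random per-SNP effects gamma_X ~ N(0, sigma2_X),
gamma_Y ~ N(0, sigma2_Y) (iid across SNPs — the infinitesimal-architecture
and InSIDE assumptions), so h2_X = m sigma2_X is the exposure's *cis*
heritability and h2_Y = m sigma2_Y the horizontal-pleiotropy variance of
the outcome. Marginal GWAS estimates from cohorts of size n_X and n_Y are

    betahat_X = C gamma_X + eta_X,                eta_X ~ N(0, C / n_X)
    betahat_Y = C (alpha gamma_X + gamma_Y) + eta_Y,  eta_Y ~ N(0, C / n_Y)

Integrating out the gammas leaves three free parameters and Gaussian
blocks

    Cov[betahat_X]            = sigma2_X C^2 + C / n_X
    Cov[betahat_X, betahat_Y] = alpha sigma2_X C^2
    Cov[betahat_Y]            = (alpha^2 sigma2_X + sigma2_Y) C^2 + C / n_Y

Note the sampling-noise blocks use C/n, not C(1 - h2)/n: the likelihood
deliberately drops the residual-variance factors (they are within a few
percent of 1 for *cis* traits). The simulator, by contrast, keeps them in
its noise terms (see below); this asymmetry is intrinsic to the method and
is the measured source of its small multiplicative estimation bias (~+2%
at alpha = 0.2 in our recovery runs). We keep both conventions rather than
"fixing" either side.

With the eigendecomposition C = U L U^T and rotated effects
delta = U^T betahat, the 2m-dimensional density factorizes into one
bivariate Gaussian per eigenvalue lambda_i:

    S_i = [[ sigma2_X l2 + lambda_i/n_X ,  alpha sigma2_X l2 ],
           [ alpha sigma2_X l2 , (alpha^2 sigma2_X + sigma2_Y) l2 + lambda_i/n_Y ]]

with l2 = lambda_i^2, and loglik = sum_i log N((deltaX_i, deltaY_i); 0, S_i).
We implement this per-component form directly (`likelihood._loglik`); it is
algebraically identical to the single printed closed-form expression in
D-matrix notation, is finite and exact at sigma2_Y = 0 (the constrained
fit needs no limiting argument: the lambda_i/n noise keeps S_i positive
definite), and is verified against an independent brute-force
2m-dimensional multivariate-normal density to 1e-6 over a 27-point
parameter grid in the test suite.

Only the leading eigencomponents holding `variance_kept` (default 0.99) of
trace(C) are retained, both to bound cost and to drop the noise-dominated
near-null space of real LD matrices. Negative eigenvalues above -1e-8 are
clipped silently; larger negative values warn (non-PSD input) and are
clipped.

## Fitting and inference

Three maximizations (Nelder–Mead, variance components on the log scale to
enforce positivity, alpha on the natural scale):

1. alpha = 0, free (sigma2_X, sigma2_Y);
2. sigma2_Y = 0, free (alpha, sigma2_X);
3. all three free.

Starts are method-of-moments: sigma2 from mean((delta^2 - lambda/n)/lambda^2)
floored at a small positive value, alpha from the rotated-effects regression
sum(deltaX deltaY)/sum(deltaX^2); the pleiotropy-sensitive fits add a
near-boundary start (log sigma2_Y = -18) and the best optimum is kept.
Tolerances are xatol 1e-4 / fatol 1e-6, which resolve log-likelihood
differences two orders of magnitude below the chi-square scale that matters
for inference.

P values for alpha and for sigma2_Y are likelihood-ratio tests with one
degree of freedom against fit 3; negative LR statistics (optimizer
round-off at a boundary optimum) are clipped to zero, giving p = 1.
Because sigma2_Y = 0 lies on the parameter boundary, the pleiotropy LRT's
null distribution is the 0.5 chi2_0 + 0.5 chi2_1 mixture; testing against
chi2_1 is therefore deliberately conservative (at most ~0.025 rejections at
the 0.05 level, and we measure 0.004–0.034 across calibration cells). The
causal-effect parameter is interior, and its test is calibrated (measured
median type-I error 0.05 across the null grid).

`se(alpha)` is a convention, not part of the published inference: we report
the numerical profile-likelihood curvature (central second difference with
the variance components re-optimized at alpha +/- h, h = 2% of
max(|alpha|, 0.05)). It feeds the meta-analysis weights; the headline
per-region inference object remains the LRT P value.

## Competitor estimators

* `wald_ratio`: by/bx with first-order se = se_y/|bx| (exposure-effect
  uncertainty ignored, standard for genome-wide-significant instruments).
* `mr_ivw`: fixed-effect inverse-variance weighting over clumped
  (r^2 < 0.01, P <= 5e-8) instruments; equals WLS of by on bx without
  intercept.
* `mr_ivw_ld`: the GLS generalization with Omega = diag(se_y) C diag(se_y);
  reduces exactly to `mr_ivw` at identity LD. Singular Omega is
  ridge-repaired (1e-8 of trace/m, escalating tenfold to 1e-4, logged).
* `mr_pca`: principal components of the weight-scaled LD matrix
  (weights bx/se_y), retaining 99% of the trace, with the GLS estimator in
  component space; equals `mr_ivw_ld` at full retention.

All competitor P values are two-sided normal.

## Harmonization and regions

Pipeline order: three-way intersection on (chrom, pos, allele pair) with
sign flips where effect/other alleles are swapped -> A/T and C/G
(palindromic) SNP removal -> reference MAF >= 0.005 -> per-trait
sample-size completeness n >= 0.95 max(n) (skipped when per-variant n is
constant or absent) -> standardization beta = z/sqrt(n + z^2),
se = 1/sqrt(n + z^2). The filters commute, so ordering only affects logged
counts; intersection first minimizes work. MAF comes from the LD reference
(the panel is the only place it is reliably defined for both studies).
Duplicate variant records keep the first occurrence, logged.

Associated regions: greedy P-value clumping (250 kb window, r^2 >= 0.01
absorbs into the index, P <= 5e-8; ties in P broken by smaller position),
each index spawns a +/-250 kb interval, and touching or overlapping
intervals on one chromosome are unioned — merged regions can therefore far
exceed 250 kb. Instrument selection for the IVW family re-runs the clump
inside a region with the distance window disabled.

Coordinates are 1-based inclusive throughout (PLINK .bim convention); BED
export converts to 0-based half-open.

## Simulator

The generator mirrors a *cis* molecular-QTL study read out against a large
outcome GWAS: defaults n_X = 10,000, n_Y = 300,000, m = 2,068 SNPs,
m_causal = 10, exact LD reference. Steps per replicate:

1. **Causal sets.** m_causal exposure SNPs; unconstrained placement is
   uniform, otherwise iterative selection with pairwise |r| within
   [r_min, r_max] of all previously selected SNPs; outcome-causal SNPs are
   drawn from the LD window (same |r| criterion) of the exposure set.
   Infeasible constraint sets raise after bounded retries, and scenarios
   with more than 25% failed replicates are reported empty.
2. **Effects.** gamma values drawn N(0, h2/m_causal) on the causal sets and
   then rescaled so the realized genetic variance gamma' C gamma equals h2
   exactly. The rescale removes between-replicate heritability jitter and
   makes the (1 - h2) residual factors exact rather than in-expectation;
   this is a convention choice the calibration tolerances are insensitive
   to.
3. **Marginals.** betaX = C gammaX + N(0, C (1-h2x)/n_X);
   betaY = C (alpha gammaX + gammaY) + N(0, C (1-alpha^2 h2x - h2y)/n_Y)
   — the outcome mean includes the alpha C gammaX term explicitly.
   Standard errors are the theoretical 1/sqrt(n) of standardized effects.

Imprecise LD references are sampled by drawing n_ref Gaussian vectors with
covariance C and taking their sample correlation — equal in distribution to
a normalized Wishart(n_ref, C/n_ref) draw and valid for n_ref < m. Non-PSD
input gets escalating diagonal regularization, capped at +0.5.

Synthetic LD (`synth_ld`) is block-diagonal AR(1): Poisson block lengths
around `block_size` (default 50), within-block decay drawn U(0.5 rho, rho)
(default rho 0.9), random symmetric sign flips for allele orientation. It
is positive definite by construction. What it does **not** emulate about
real LD: long-range inter-block correlation, allele-frequency-dependent LD
strength, rank deficiency from finite reference panels, and population
structure. Calibration results on it therefore demonstrate statistical
correctness of the estimator under the model, not robustness to real-panel
pathologies (the imprecise-LD and correlated-pleiotropy scenarios probe
those separately).

## Meta-analysis and benchmark metrics

Fixed-effect combination across k regions: alpha_bar weighted by se^-2 and
se(alpha_bar) = 1/sqrt(sum se^-2), the standard fixed-effect form (note
the reciprocal: without it the pooled se would grow with k). Cochran's
Q = sum ((alpha_r - alpha_bar)/se_r)^2, approximately chi2 on k-1 df under
homogeneity. Detection rate is the fraction of P values strictly below a
threshold (type-I error under null scenarios, power under causal ones);
AUC is the rank-based Mann–Whitney statistic treating smaller P as more
causal; precision/recall are computed at a caller-supplied (Bonferroni)
threshold.

## Problem sizes in the shipped calibration runs

The acceptance script and the calibration tests use a 500-SNP synthetic
region with ~50-SNP blocks and 500 replicates per grid cell (tests reduce
the grid to 6 cells; the script runs the full 18-cell null grid). These
sizes give binomial Monte-Carlo error of ~0.01 on a 0.05 rejection rate,
which is the resolution at which the claims are stated. Parameter recovery
uses 200 replicates per alpha value.

## Known limitations

* The ~+2% multiplicative bias of alpha-hat discussed above, inherited from
  the likelihood's dropped residual-variance factors.
* The pleiotropy test is conservative by construction (boundary null);
  its measured rejection at negligible pleiotropy is 0.004–0.034 rather
  than the nominal 0.05.
* Hard-call PLINK-1 genotypes only; no VCF/BGEN, no liftover, no dosage
  data.
* Single exposure only; no multi-exposure extension.
* se(alpha) from profile curvature can be NaN when the profile is locally
  flat (non-positive curvature); the LRT P value remains valid.
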