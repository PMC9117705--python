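# Methods notes

This note records the statistical model behind each component, the
numerical choices, the defaults and their rationale, and the known limits
of the synthetic-data harness.

## Setting and assumptions

For one gene with SNPs i = 1, …, k, the inputs are two-sided p-values
p₁, …, p_k and a k×k allelic-correlation matrix R (the "LD map").  All
methods test the joint null that every SNP-level null holds, assuming each
pᵢ ~ Uniform(0,1) marginally under its null — true only asymptotically for
the trend tests that typically produce these p-values.  The dependence
model throughout is that the latent SNP test statistics are multivariate
normal with correlation matrix R; this is what both the pseudo-permutation
null and the Brown/Strube covariance kernels assume.

p-values of exactly 1 are accepted; inputs are clamped to
[1e-300, 1 − 1e-16] before log or quantile transforms, and Φ⁻¹(1 − p) is
always computed as −Φ⁻¹(p) through the lower tail so small p-values keep
full relative accuracy.  Zero p-values are rejected at ingest because
ln p and the quantile transform are undefined there.

## Base combiners

Bonferroni, Tippett, binomial ("excess significance": r = #{pᵢ ≤ α_p}
against Binomial(k, α_p)), Fisher and Stouffer, exactly in their textbook
forms.  Defaults: the binomial per-SNP threshold α_p = 0.05 (the
conventional pointwise level; exposed as a parameter).  Ties pᵢ = α_p
count as significant (the count is of SNPs *significant at* α_p).  No
across-gene multiple-testing correction is applied inside the combiners;
a genome-wide analysis would Bonferroni-correct the gene-level p-values
afterwards.

## Effective number of tests

All four estimators work on the eigenvalues of the symmetrised R, without
positive-definiteness repair: Li & Ji uses |λ| and Galwey max(0, λ) by
construction, and Nyholt/Gao are well defined for any symmetric matrix.
Choices that the literature leaves ambiguous:

- Nyholt's Var(λ) uses the sample variance (divisor k−1), matching the
  original proposal; a `ddof` switch selects the population variance.
- Gao's C defaults to 0.995.  On an identity matrix the estimator returns
  less than k whenever k(1−C) > 1 (an inherent property, not a bug).
- Fractional k_eff (Nyholt, Galwey) is used as-is everywhere the formulas
  allow it — the chi-square accepts non-integer degrees of freedom — but
  the binomial test needs an integer trial count, so there k_eff and the
  rescaled significant count r·k_eff/k are floored.  Flooring errs on the
  conservative side, which we prefer to a liberal test.

## Brown and Strube covariance kernels

The pairwise covariances
Cov(−2 ln pᵢ, −2 ln p_j) and Cov(Φ⁻¹(1 − pᵢ), Φ⁻¹(1 − p_j))
are two-dimensional integrals against the bivariate standard normal
density with correlation ρ.  For two-sided p-values p = 2(1 − Φ(|z|)) the
integrand depends on |z| only; we fold the integral into the positive
quadrant and apply Gauss–Legendre quadrature with 48 nodes per panel on
the per-axis panels (0, 1e-4, 1e-2, 0.1, 0.5, 1, 2, 3.5, 5, 8).  The
graded panels near zero absorb the square-root-log singularity of the
Stouffer-scale transform Φ⁻¹(2Φ(|z|) − 1) at z = 0; truncation at 8
standard deviations is far below the 1e-6 accuracy target.  Node-doubling
and a 1e7-draw Monte Carlo oracle bound the absolute error under 1e-6 for
all |ρ| ≤ 0.999.  The one-sided Fisher integrand is smooth, so a rotated
200-node Gauss–Hermite rule (u = zᵢ+z_j, v = zᵢ−z_j directions, which
diagonalise the correlation) is used instead.

Beyond |ρ| = 0.999 the exact degenerate limits take over: 4 for the
Fisher scales at ρ = ±1 (Var(−2 ln p) for uniform p), 1 for the two-sided
Stouffer scale, and 4(2 − π²/6) − 4 for the one-sided Fisher kernel at
ρ = −1.  The two-sided covariance integrand is symmetric in zᵢ and z_j by
construction — both factors are ln 2(1 − Φ(|·|)) — and the Monte Carlo
oracle confirms this form.

Because a gene needs k(k−1)/2 kernel evaluations, the default path reads
a lazily built lookup table on a 0.001-spaced ρ grid with monotone cubic
(PCHIP) interpolation (built once per process, a few seconds); exact
per-pair quadrature is available via `exact=True`.  Interpolated values
are clipped to each kernel's attainable range before summation so that
accumulated interpolation error can never drive Var(X²) negative.

Brown's method then refers X² to c·χ²_f with c = Var(X²)/2E(X²),
f = 2E(X²)²/Var(X²); Strube's method divides Stouffer's numerator by the
square root of k + 2ΣCov.  Note that Brown's fit matches two moments
only: it is *not* exact under the MVN null, and its p-values can differ
from the exact (pseudo-permutation) null probability by a few percentage
points in the bulk of the distribution even though its rejection rate at
conventional α levels is nominal.  The test suite asserts the
calibration property; bulk-level agreement with the empirical null should
not be expected of a two-moment approximation.

## Pseudo-permutation empirical null

Sampling uses a Cholesky factor when R is positive definite; otherwise R
is first projected to the nearest positive-definite correlation matrix
(alternating projections with unit-diagonal constraint, eigenvalue floor
1e-8, delegated to statsmodels' `corr_nearest` with a final exact
spectral floor), the repair is recorded in the output metadata, and the
repaired matrix is used for *all* downstream computations (empirical,
Brown, Strube) for internal consistency.  The estimator is the plain
tie-inclusive fraction Σ I(p_j ≤ p_obs)/s, which can return exactly 0; a
`plus_one` option gives (1 + count)/(1 + s) for log-scale downstream use.
Results are bit-reproducible given a seed.  s defaults to 1e5 for
single-gene reports (1e4 inside the simulation harness); below 1000 a
warning is emitted.

## Synthetic genotypes and the simulation harness

Genotypes come from a latent-Gaussian threshold model: two latent
haplotype vectors per individual ~ MVN(0, Σ) with Σ an AR(1),
exchangeable, block or identity structure; a latent value below Φ⁻¹(MAF)
becomes a minor allele; alleles sum to the 0/1/2 dosage.  LD profiles are
therefore specified on the *latent* scale; thresholding attenuates the
realised allelic correlation (e.g. latent AR(1) ρ = 0.8 at MAF 0.3 yields
adjacent r ≈ 0.58), which is deliberate: real LD maps are estimated from
genotypes, so the harness always re-estimates R from the simulated
genotypes rather than trusting the latent target.  Columns that come out
monomorphic trigger a full redraw (bounded retries) so the joint LD
structure is never patched column-wise.

Default study conditions mirror a small case-control design: n = 102
individuals per gene, MAF drawn uniformly from [0.1, 0.5], per-SNP
Cochran–Armitage trend tests (asymptotic normal form, scores 0/1/2;
degenerate tables return p = 1), 1000 replicates per gene, α = 0.05.
The null phenotype is iid Bernoulli(0.5).  Alternatives use a logistic
model with the intercept set to minus the mean linear predictor so that
about half the sample are cases; the causal set is a single random SNP,
or 5%/20% of SNPs (floored at 1) placed either consecutively from a
random start ("compact") or equally spaced; the effect size (0.2 or 0.5
on the log-odds scale per minor allele) is optionally divided across the
causal SNPs ("distributed").  In single-SNP scenarios the causal SNP is
re-selected each iteration (a flag restores a fixed choice).  Sample
sizes other than the gene's own trigger bootstrap resampling of
individuals per replicate; the LD map and everything derived from it stay
fixed at the original-sample estimate, as they would when a reference
panel supplies the LD information.  HWE violations are not filtered; the
trend test does not require the assumption (the EM-based LD estimator
does, which is why the dosage-correlation estimator is the default).
Per-gene RNG substreams are spawned from the master seed, so results are
independent of gene ordering.

The acceptance-scale studies use deliberately reduced problem sizes — 27
genes (k ∈ {5, 20, 100} × latent ρ ∈ {0, 0.5, 0.9}, three genes each) at
1000 null replicates, and 10 genes at 400 replicates per power cell —
chosen as the smallest sizes at which the qualitative orderings of
interest are separated by many Monte Carlo standard errors.

What the harness does *not* emulate about real data: haplotype-block
structure from recombination hotspots (AR(1)/block latent LD is a smooth
caricature), allele-frequency spectra skewed toward rare variants,
genotyping error and missingness (inputs are assumed complete and
imputed upstream), population stratification, and negative LD patterns
beyond what the latent model produces.  Passing tests therefore establish
the methods' behaviour under the MVN-latent model, not under every real
LD configuration.

## Interfaces

File formats are plain text: one/two-column p-values, square delimited LD
maps, 0/1/2 genotype tables, minimal diploid VCF (read via cyvcf2; sites
oriented so code 2 is the minor-allele homozygote; missing or
non-biallelic records rejected).  Output indices are 1-based SNP ordinals
within the gene; genomic positions are carried as labels only.  Tabular
outputs are tab-separated with '.' for not-applicable cells and
shortest-round-trip float formatting.  The `ldpool` CLI is a thin layer
over these functions; exit code 0 on success, 1 with a one-line
diagnostic on any parse or validation failure.

## Known limitations

- Brown's closed-form covariance approximation is intentionally not
  implemented; numerical integration is the single code path.
- Weighted Fisher/Stouffer variants and one-sided SNP p-values are out of
  scope (GWAS association tests are two-sided).
- The empirical estimator has resolution 1/s; extreme gene-level
  p-values need the analytic methods or a larger s.
- No genome-wide orchestration (gene assignment, imputation, phasing,
  per-chromosome k_eff) — the unit of analysis is one gene.
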