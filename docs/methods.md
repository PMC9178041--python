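# Methods

This note documents the statistical models implemented in `gxemeta`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The interaction model and its tests

Every per-SNP analysis starts from ordinary least squares on

    Y = β₀ + β_G·G + β_E·E + β_GE·G·E + ε,   ε ~ N(0, σ²)

with an intercept as the only covariate. Standard errors are model-based
(homoskedastic) by default; `fit_interaction_model(..., robust=True)`
switches to the HC0 sandwich. The original multi-cohort analyses this
mirrors were not uniform in that respect, so the default is a package
decision, not a fact about any particular study.

The 1df statistic is (β̂_GE/se)² against χ²₁; the 2df statistic is
b′V⁻¹b with b = (β̂_G, β̂_GE) and V their 2×2 covariance, against χ²₂.
Only the (β̂_G, β̂_GE) covariance block is carried downstream; β̂_E is
estimated but nothing consumes it. Two-sided tests throughout.

For a binary 0/1 exposure with no further covariates, the interaction
model is exactly equivalent to two per-stratum regressions:
β̂_G equals the OLS slope among the unexposed, β̂_G + β̂_GE the slope
among the exposed, with variance var(β̂_G) + var(β̂_GE) + 2·cov. This
identity is tested exactly and is how stratified summary statistics are
derived without individual-level refits.

Degenerate designs (monomorphic SNP; everyone exposed, which makes G·E
collinear with G) raise `DegenerateDesignError` in the single-SNP API and
are excluded with a logged reason by the genome-scan wrapper. Noiseless
inputs (a zero residual) are allowed for exactness tests: coefficients
are returned exactly and the saturated tests report p = 0 (or 1 at the
null).

Fitting is closed-form on sufficient statistics, batched across SNP (or
replicate) columns as stacked 4×4 normal-equation solves. That is what
makes the 10,000-SNP null calibrations and 2,000-replicate bias scenarios
run in seconds on one CPU; statsmodels OLS is used in the test suite as
an independent single-SNP oracle, never in the computational path.

## Meta-analysis

Fixed effects only. The 1df scheme inverse-variance-weights β̂_GE with
Cochran's Q for heterogeneity (k = 1 reports a missing, not unit,
heterogeneity p). The 2df scheme is GLS: V_meta = (ΣV_k⁻¹)⁻¹,
b_meta = V_meta·ΣV_k⁻¹b_k. Sums inside the IVW combination use
compensated (fsum) accumulation so study order is exactly irrelevant.

When combining tables, SNPs are harmonised to the first table's effect
allele: a strand-unambiguous swap negates the betas and reflects the
frequency; palindromic A/T and C/G variants are dropped with a warning,
since strand cannot be resolved without external information. Stage
combination keys on (chromosome, position) so that incompatible allele
pairs at one site are rejected loudly rather than passed through.
Combined records keep the interaction coefficient from the 1df IVW track
and the main effect from the 2df GLS track — deliberately, because of the
bias documented below.

The set-level `mean_chi2_test` refers the sum of k independent 1df
chi-squares to χ²_k; the sum form (rather than a normal approximation to
the mean) is the implemented and reported convention.

## Bias of the joint 2df meta-analysis under heterogeneity

With two cohorts that differ jointly in main genetic effect and exposure
prevalence, the per-cohort interaction estimates remain unbiased, and so
does their IVW combination. The GLS 2df combination, however, resolves
the between-cohort main-effect gradient partly into the interaction
coordinate (the per-cohort (β̂_G, β̂_GE) covariances are correlated with
the exposure distribution), biasing the combined interaction estimate and
inflating its Wald test. `bias_sim.run_null_scenario` measures both the
estimate-scale bias and the test-scale inflation with exact
Clopper-Pearson intervals; in the default contrast (Δβ_G = 0.5,
prevalence 0.2 vs 0.8, n = 5,000 per cohort) the 2df-GLS rejection rate
at α = 0.05 approaches 1.0 while 1df-IVW stays inside the exact binomial
99% band. Scenario sizes (n = 5,000, 2,000 replicates) were chosen so the
contrast is unambiguous yet runs in seconds; replicates with a degenerate
cohort (e.g. no unexposed individuals drawn) are dropped and counted.

A related design fact, also simulated: the main effect β_G is the effect
at E = 0. A binary exposure anchors it with the unexposed point mass; a
continuous exposure concentrated around a nonzero mean leaves it an
extrapolation, so its estimate is noisier at matched mean and sample
size.

## Signals, loci, power

Clumping is greedy: take the smallest-p unassigned SNP below the
significance threshold (5×10⁻⁸ default) as lead, absorb unassigned SNPs
within ±500 kb with panel r² ≥ 0.2, repeat. Ties on p break by ascending
(chromosome, position), making the output exactly invariant to row
order, and every significant SNP lands in exactly one signal. LD comes
from a user-supplied dosage panel; no external reference is bundled.

Loci are ±500 kb windows around signals, clipped at position 1, merged
when they overlap *or touch* — merging at exact 1 Mb separation avoids a
one-basepair ambiguity — giving pairwise-disjoint intervals of ≥1 Mb.
Positions are 1-based inclusive in memory; the BED-like TSV on disk is
0-based half-open, converted (and round-trip tested) at the boundary.

Power uses the noncentral chi-square with ncp = N × (variance fraction
explained); df = 1 is evaluated by the exact normal form
Φ(√ncp − z_c) + Φ(−√ncp − z_c). The df of the test is an explicit
argument everywhere: the five reported study designs imply a common
noncentrality near 42, which sits between the df = 1 and df = 2
requirements for 80% power at α = 5×10⁻⁸, so the intended convention is
ambiguous and is exposed as a parameter rather than guessed. The
acceptance script reports the power under both conventions.

## Enrichment and aggregate tests

Pre-clumped (independent) SNPs are binned by marginal p-value into decade
bins (1, 0.1], (0.1, 0.01], …; each bin reports the proportion with
interaction p < 0.05, its Wilson score interval, and null reference
Wilson bands around 0.05 at band levels 0.05 and 10⁻⁴. Empty bins report
a missing proportion, never 0. A cumulative (threshold) mode mirrors the
p ≤ t presentation.

Direction classification within a phenotype-exposure-ancestry trio:
concordant when marginal and interaction effects share a sign (enhanced
effect among the exposed), discordant otherwise, and "opposite" when
β_G + β_GE has the opposite sign of β_G (effect reversal between
strata). The marginal effect proxies the main effect here because it is
independent of the interaction estimate under the null. Coefficients that
are exactly zero — a probability-zero event in continuous data but
reachable in synthetic edge cases — are excluded from concordance counts.
All binomial tails are exact (`scipy.stats.binomtest` / `binom.sf`),
never normal approximations: the trio test is the exact two-sided
binomial against 0.5, and the cross-trio accumulation is the exact
one-sided upper tail P(X ≥ k | n, 0.05) with a 0.05/n Bonferroni
threshold.

Aggregate set tests on summary statistics: omnibus Σz² against χ²_k,
unweighted GRS z = Σβ̂_GE/√(Σse²), weighted GRS with externally supplied
(marginal-effect) weights after allele harmonisation. Their exact
supplementary-level specifications are not fully public; the forms here
are the standard summary-statistic versions and are labelled as such.

## Variance explained

Under HWE, G ⟂ E and independent SNPs, with var(G) = 2f(1−f) and
μ_G = 2f:

- binary E (prevalence p): var(GE) = p(varG + μ_G²) − p²μ_G²,
  cov(G, GE) = p·varG;
- continuous E (μ, σ²): var(GE) = varG(σ² + μ²) + μ_G²σ²,
  cov(G, GE) = μ·varG.

r²_marginal = Σβ̂_M²varG/var_Y; r²_joint sums the full quadratic form of
(β̂_G, β̂_GE); r²_interaction is joint minus marginal, floored at zero
with a flag when sampling noise drives it negative, and the pure term
Σβ̂_GE²var(GE)/var_Y is reported alongside. The convention is the
*unconditional* variance of the genetic predictor β_G·G + β_GE·G·E,
which matches a direct Monte-Carlo variance of that predictor. One
consequence, documented rather than hidden: recoding the effect allele
moves a 2β_GE·E term into the exposure main effect, so r²_joint shifts
by exactly (μ_G′² − μ_G²)β_GE²var(E) under an allele flip while
r²_marginal is flip-invariant; the test suite asserts this identity.
var_Y defaults to 1 (standardized traits). SNP independence is the
caller's responsibility — clump first.

The significance of the interaction component is the chi-square
approximation to the joint test of all interaction coefficients,
Σ(β̂_GE/se)² against χ²_k.

## LD-score regression

Plain fit: weighted regression of χ² on N·ℓ/M with a free intercept;
the slope is h². Weights are 1/max(ℓ_j, 1) — a deliberate simplification
of the reference tool's combined heteroskedasticity/correlation weights —
and uncertainty comes from a delete-a-block jackknife over 200 contiguous
SNP blocks (both configurable). Constant LD scores are rejected as
unidentifiable.

Partitioned fit: regression on per-annotation LD scores gives
coefficients τ_c; per-annotation heritability h²_c sums the per-SNP
heritability over members, and enrichment is (h²_c/h²)/(M_c/M) with a
jackknife p-value on the difference between the heritability share and
the SNP share. The normal equations are solved by minimum-norm least
squares because a base annotation plus a partition of it is exactly
collinear; the derived h²_c and enrichments are invariant to that null
space (the test suite checks the disjoint-partition consistency
Σh²_c = h² explicitly). The annotation significance threshold is always
recomputed as 0.05 / (number of annotations tested), never hard-coded.

Stratum comparison: the heritability difference test is the two-sample
Wald z on independent strata. The heterogeneity-filter sensitivity curve
refits h² after dropping SNPs with heterogeneity p below each threshold;
the "selected" estimate is defined operationally — the largest-retention
fit whose intercept is within 2 jackknife SEs of 1 — because no published
rule exists. Enrichment comparison between strata reports per-group
differences of median enrichments (unexposed minus exposed), the pooled
share of nominally significant annotation tests, and the Pearson
correlation of the enrichment vectors, excluding the base annotation
whose enrichment is identically 1.

## The synthetic data generator

Genotypes: per SNP, a standard normal latent variable is double-
thresholded at the HWE cumulative probabilities (1−f)² and 1−f², so
marginals are exactly Hardy-Weinberg; within an LD block the latents
share an equicorrelation ρ (one common factor), giving tunable positive
dosage LD; blocks are independent. The default frequency spectrum is
Uniform(0.05, 0.5) — low-frequency variants are filtered in the analyses
this emulates, and no published spectrum exists to copy. Exposures are
Bernoulli(p) or Gaussian and independent of genotype (the interaction
model assumes no G-E correlation). Phenotypes follow the linear
interaction model at designated causal SNPs. All streams derive from a
single master seed with fixed offsets; identical spec + seed gives
bit-identical output.

LD-score summary statistics are drawn as χ²_j = z²_j with
z_j ~ N(0, 1 + N·h²·ℓ_j/M), or with the annotation model variance
1 + N·Στ_c·ℓ(j,c); a noiseless mode returns the expectation itself for
exactness tests.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: realistic recombination maps or negative
LD, imputation uncertainty (dosages are hard calls), population
structure and relatedness, covariates beyond the intercept and exposure,
assortative or G-E-correlated exposures (a dependence knob exists but
defaults off), and case-control/liability-scale traits. Simulation sizes
throughout (e.g. n = 5,000 per cohort, 2,000 replicates; M = 20,000 SNPs
for heritability recovery) are desk-scale choices that make every
property decisive yet fast; they are not the sample sizes of any real
consortium.

## Numerical conventions

- Rank deficiency is detected by a scale-invariant condition-number
  check (threshold 10¹²) in the OLS core; batched fits flag degenerate
  columns instead of failing the scan.
- Clumping ties on p break by (chromosome, position) ascending.
- IVW accumulations use fsum; permutation invariance is exact.
- p-values of saturated (noiseless) tests are 0/1 by convention.
- Wilson bounds are clamped exactly to 0 at x = 0 and 1 at x = n.
- The pipeline's artifacts are byte-deterministic given config + seed;
  manifests record a config hash and the package version.
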