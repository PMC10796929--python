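# Methods

## The model

`trajgwas` analyses repeated cognitive measurements with a piecewise-linear
("knot-point") trajectory model. For subject *i* at time *t* (days since
baseline) the mean of the z-scored outcome is

    E[y_it] = β0 + β_age·(age_i − age_ref) + β_s1·s1(t) + β_s2·s2(t)

with spline columns `s1(t) = min(t, 365)/365` and
`s2(t) = max(t − 365, 0)/365` (years), so β_s1 is the average change per
year between baseline and the knot at one year, and β_s2 the average change
per year from the knot to the end of follow-up. Baseline age is centred at a
reference (by default the sample mean; the synthetic default is 73.4 years)
so the intercept is the expected score of an average-aged subject at
baseline.

For the GWAS, each variant *g* enters as an additive dosage with
interactions against all four trajectory parameters:

    … + γ0·g + γ_age·g·(age_i − age_ref) + γ1·g·s1(t) + γ2·g·s2(t)

Each variant is fitted in its own model; the four γ terms are reported as
beta / robust SE / two-sided Wald p per variant ("intercept", "age",
"slope 1", "slope 2" blocks). An optional 4-df joint Wald test over the
quadruple is available as an extra column; the per-parameter tests are
primary.

## Estimation: GEE with a sandwich, and why it is written from scratch

Repeated measures within a subject are correlated; the scan treats that
correlation as a nuisance via generalised estimating equations (Gaussian
family, identity link). The solver iterates weighted least squares under a
working correlation (independence, exchangeable, or unstructured on a
shared visit grid) with moment re-estimation of the dispersion and the
correlation parameter from Pearson residuals, until the coefficient change
falls below 1e-8 (max 50 iterations). Non-convergence is recorded on the
fit and flagged in scan output rather than raised — a genome-wide scan must
not abort on one variant. Missing visits are handled by subsetting the
working correlation to each cluster's observed occasions (for
exchangeable this is implicit in the closed-form inverse).

The estimator is implemented directly on per-cluster sufficient statistics:
for independence/exchangeable every quantity reduces to grouped sums
(`np.add.reduceat`) and the exchangeable inverse uses Sherman–Morrison, so
one fit on ~3,000 rows costs a few milliseconds and a 10,000-variant scan
runs in about a minute on one core. A general-purpose GEE (statsmodels) is
used in the test suite as an independent oracle — betas, sandwich SEs and
the exchangeable correlation agree to ~1e-10 — but not in the scan path.

Standard errors are the sandwich A⁻¹BA⁻¹ (A the model-based information, B
the empirical score outer product over clusters), valid under working-
correlation misspecification. **Small-sample correction:** with a few
hundred clusters the uncorrected sandwich is anti-conservative — in our
null calibration runs at 500 subjects the empirical SD of the null betas
exceeded the mean robust SE by 3–8% and the α=0.05 rejection rate reached
0.062 for the age-interaction term. The scan therefore defaults to the
Mancl–DeRouen bias correction (per-cluster residuals inflated by
(I−H_i)⁻¹ before forming B), computed in batches of equal cluster size so
it stays cheap inside the scan. After correction the null rejection rates
sit at 0.047–0.055 and the maximum genomic-control lambda at 500×10,000 is
≈1.0. `fit_gee` itself defaults to the classic uncorrected estimator
(matching geepack/statsmodels semantics); only the scan layer switches the
correction on. At several thousand clusters the two are practically
identical.

The working correlation for the scan defaults to exchangeable:
it is robust to irregular visit grids, the sandwich protects against
misspecification, and stage-1 exploration can still use the unstructured
option when visits lie on the shared 6-month grid.

For model exploration and polygenic-score testing a REML linear mixed model
(random intercept + random slope on total time) is provided, wrapping
statsmodels MixedLM and reporting variance components. For Gaussian
outcomes GEE and LMM estimate the same fixed effects; the tests verify
agreement to 0.02 z-units on simulated data, and the PRS association falls
back to GEE when REML does not converge.

## Phenotype preparation

Raw test scores are z-standardised to the baseline (day 0) mean and sample
(n−1) SD of each test; later visits reuse the baseline parameters. A test
with constant baseline scores cannot be standardised and is reported by
name. Domain scores average the available component z-scores
(available-case averaging when components are missing; a cell with no
components is dropped and logged); the global composite averages the five
domain scores. The component-to-domain map is configurable; the default
uses five domains (attention, executive, memory, learning, language) with
two synthetic tests each.

## Genotype QC

Per-variant filters, each with its conventional default: call rate ≥ 0.95,
HWE exact-test p ≥ 1e-8, MAF ≥ 0.01, imputation r² ≥ 0.7, and expected
minor allele count EMAC = 2·N·MAF·r² > 200. The EMAC rule is sample-size
dependent: at N = 2515 with r² = 1 it corresponds to MAF just above 4%
(2·2515·0.04 = 201.2); toy cohorts must scale it down or it excludes
everything (the pipeline raises a clear error in that case). The exclusion
ledger records the first failing rule per variant in a fixed order
(call rate, HWE, MAF, r², EMAC), so the excluded set is partitioned.

The HWE test is the exact conditional test on the heterozygote count given
the allele totals, with the distribution built by the standard ratio
recursion in log space; the test suite checks it exhaustively against a
closed-form log-gamma enumeration for all configurations with up to 200
subjects. Dosages are rounded to hard genotypes for this test (a config
switch skips HWE for imputed dosages, where rounding is not meaningful).

Ancestry principal components are computed from dosages standardised as
(d − 2p)/√(2p(1−p)) (monomorphic variants dropped, missing dosages
mean-imputed), via SVD; scores are left singular vectors scaled by singular
values. An every-k-th-variant thinning stands in for LD pruning.

## Selection diagnostics

A cohort screened on age and genotype is a collider: within the enrolled
sample, selection induces an association between age and the
selection-driving genotypes that cannot be causal. The diagnostic runs a
GWAS of baseline age (per-variant simple OLS with HC0 robust SEs; age is
treated as a continuous outcome) and of sex (per-variant logistic
regression, batched Newton across variants with divergence flagged as
separation) among included subjects, one row per subject. Variants with
p < 5e-8 on either trait are flagged and carried as covariates into the
trajectory scan; a variant conditioned on itself is reported with p = 1
(no residual association, by construction). The scan's covariate set also
always contains the two a-priori risk loci; the diagnostic validates that
choice rather than replacing it. Lifestyle covariates (education, alcohol,
smoking, BMI) are deliberately excluded from the scan because they are
plausibly downstream of genotype and adjusting for them can itself open
collider paths; an override flag exists.

## Clumping and look-ups

Significant variants for one parameter are grouped greedily: rank by
ascending p (ties by chromosome, then position — determinism), take the
best unassigned variant as an index, absorb unassigned significant
variants on the same chromosome within 1000 kb with pairwise r² ≥ 0.1
(squared Pearson correlation of dosage columns), repeat. External variant
lists are looked up with effect-allele harmonisation (betas negated when
the external effect allele is the scan's non-effect allele), "not tested"
rows for absent variants, and a Bonferroni threshold of
α/(n_variants × 4 parameters).

## Polygenic scores

Weights tables are filtered to genome-wide significant sources (p < 5e-8
only — no threshold expansion, to limit pleiotropic variants),
strand-ambiguous A/T and C/G variants are dropped, weights are aligned to
the cohort's alt allele (negated when the external effect allele matches
the cohort ref), and the surviving set is LD-clumped against the cohort's
own genotypes (cohort LD, not source-GWAS LD — the difference is noted
here; at genome-wide-significant sparsity it is rarely material). The
score is the weighted dosage sum, standardised in-sample so association
betas are per SD of score; missing dosages are mean-imputed per variant.
Association with the four trajectory parameters uses the same design as
the scan with the score in place of the dosage, fitted by REML LMM with a
GEE fallback.

## The synthetic cohort generator

The generator defines the study conditions the tests and calibration runs
operate under; it emulates a risk-stratified prevention trial of
cognitively normal older adults:

- **Ages** 65–83 at baseline, truncated normal with mean 73.4 and SD 5.3.
- **Visits** every 182.5 days to day 1825 — 11 scheduled occasions — with
  monotone missing-at-random dropout at 0.13 per visit, giving a mean of
  ≈5.9 occasions per subject (matching 20,440 rows over 3,465 subjects)
  and 1–11 occasions always.
- **Genotypes** drawn from Hardy–Weinberg proportions at frequencies
  uniform in (0.05, 0.5) by default; optional LD blocks copy a block
  anchor with a small per-subject refresh probability (block members then
  have r² near 1 − these exist so clumping and linked-selection logic can
  be tested). Imputation r² is metadata sampled in (0.55, 1].
- **Selection**: logit P(include) = b0 + a·(age − 73.4) + r·(d₁ + d₂) over
  the two designated risk loci (ordinary biallelic stand-ins for the
  APOE/TOMM40 risk haplotypes; poly-T genotyping is out of scope). All
  three parameters zero (the null default) means everyone is included.
  The `trial_selection` preset (a = 0.4, r = 2.0, b0 = −3) approximates a
  steep, near-threshold eligibility rule — the regime in which the
  collider-induced genotype–age association is unambiguous.
- **Trajectories**: latent cognition follows the two-slope mean curve
  (defaults: intercept 0, age gradient −0.03/year of age, slope 1
  +0.15/year, slope 2 +0.02/year — older subjects score lower at baseline;
  scores drift slightly upward on study) plus N(0, 0.8²) random
  intercepts, N(0, 0.07²) random slopes per year, and visit-level
  residuals with SD 0.5 (independent by default; exchangeable or AR(1)
  structures available — the within-subject correlation magnitudes are
  free parameters, as no reference values are available). Genetic effects
  are per-allele additive on any of the four trajectory parameters, in
  latent-SD units. Raw test scores are affine rescalings of the latent
  value plus N(0, 0.3²) test noise, so baseline standardisation is a real
  operation. With the default noise scales the baseline latent SD is ≈1.0,
  so simulated γ values and estimated z-scale betas are directly
  comparable (tests convert exactly using the config's variances).

What the generator does **not** emulate: practice effects beyond the
linear slope-1 drift, informative dropout (off by default; MAR given
covariates), genotyping batch structure, population stratification beyond
what the PCA test constructs explicitly, and real LD patterns. Passing
tests therefore demonstrate the estimator's statistical properties under
the assumed data-generating process, not robustness to every feature of
real trial data.

## Problem sizes and numerical choices

Calibration and acceptance runs use scaled-down panels chosen as the
package's own verification conditions: the null-scan calibration uses 500
subjects × 10,000 independent variants (lambda's sampling SD at 10,000
variants is ≈0.02, tight enough to detect miscalibration of a few
percent); effect-recovery coverage uses 100 replicates of 2,000 subjects;
the selection diagnostic uses 6,000 candidates × 8,000 variants for the
strong-selection run and 100 replicates of 600 × 1,200 for the
family-wise null rate. Convergence tolerance is 1e-8 on the max
coefficient change; exchangeable α is clipped to (−1/(n_max−1), 0.99);
ties in clumping break by (p, chrom, pos); monomorphic variants are
errors in single-variant calls and logged skips in scans; all randomness
flows from a single seed with substreams spawned per pipeline stage.

## Known limitations

- Gaussian outcomes only (no binomial/Poisson GEE families, no GEE2).
- AR(1) working correlation is not offered in the estimator (the
  generator can produce AR(1) residuals; the sandwich covers the
  misspecification).
- The unstructured working correlation requires a shared discrete visit
  grid and loops per cluster — intended for stage-1 model exploration,
  not scans.
- PRS clumping uses cohort LD; with an external reference panel the
  retained set could differ.
- The exact HWE test requires hard genotype counts; for imputed dosages
  it is applied to rounded values or skipped by configuration.
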