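# Methods

## Score construction

The genetic predisposition score is the standard weighted risk-allele
construction: with dosages g_ij counting effect (BMI-raising) alleles and
per-allele weights beta_i in kg/m²,

    GPS_j = (L / sum_i beta_i) * sum_i beta_i * g_ij .

The rescaling makes the score read in risk-allele units (0 ≤ GPS ≤ 2L for
nonnegative weights) and makes it invariant to multiplying all weights by a
positive constant. With equal weights it reduces to the plain allele count.
The phrase "rescaled to reflect the number of risk alleles" admits a
mean-weight variant (divide by the mean beta rather than L/sum); the two
are algebraically identical, which is why only one is implemented.

Missing-data rules, in order: (1) samples with a missing-call fraction
strictly above 10% of loci are excluded (31 loci: ≥ 4 missing excluded,
≤ 3 retained); (2) remaining missing dosages are replaced by the variant's
mean observed dosage, computed over non-excluded samples only. Deciding
exclusion before imputation prevents heavily missing individuals from
entering the imputation means. "Mean dosage" rather than 2×(allele
frequency) is used; the two coincide under HWE with complete data and
differ negligibly otherwise.

## Association models

All continuous outcomes are fitted by OLS with an additive genetic term
(dosage or GPS), adjusted for age, gender, smoking, physical activity and
alcohol, optionally plus BMI. Gender, smoking and physical activity enter
as indicator contrasts against their first (lowest) level; level order is
fixed so fits are bit-reproducible. Analyses are complete-case per model,
and each result reports the n actually used. Glucose, insulin, HOMA-IR and
HOMA-B are natural-log transformed (base unstated in common practice;
natural log chosen, coefficients reported on the transformed scale).

Confidence intervals use the fixed normal multiplier 1.96 rather than t
quantiles: at n ≈ 1500 the difference is below 0.2% of the SE and the
simpler convention matches how such tables are usually printed. Logistic
models use Wald p-values and OR = exp(beta); complete separation and
non-convergence are hard errors with diagnostics rather than silent
garbage.

The Hardy-Weinberg test is the 1-df chi-square against expected counts
(p², 2pq, q²) from the observed allele frequency; monomorphic variants
return chi2 = 0, p = 1 with a warning rather than an error, since an
all-missing or fixed locus is a data problem reported elsewhere.

The directional-consistency test treats each locus's estimated sign as a
Bernoulli(1/2) draw under the null. The default method is the one-sided
normal approximation without continuity correction,
p = Phi(−(k − n/2)/sqrt(n/4)), which for 25/31 gives 3.2e-4 (prints as
0.0003); the exact binomial tail (4.4e-4 for 25/31) is exposed as an
alternative and is verified against brute-force enumeration in tests.

Interaction tests add the modifier (numeric-coded, so a 3-level factor is
tested as a linear-by-score trend) and the score × modifier product to the
adjusted model and report the product term. Variance explained is computed
as three OLS fits (score alone, covariates alone, both) on one shared
complete-case sample, so the R² values are directly comparable and the
score's increment is full − covariates.

## Power

Single-SNP power uses the large-sample normal framework (as in the Quanto
program): predictor variance 2·maf·(1−maf) under HWE, noncentrality
z* = beta·sqrt(n·2·maf·(1−maf))/sigma_resid with sigma_resid² =
trait_sd² − beta²·2·maf·(1−maf). Score power uses the Fisher-z
approximation on the implied correlation r = beta·score_sd/trait_sd (or
sqrt(r²)): power = Phi(atanh(r)·sqrt(n−3) − z_crit). Both are normal, not
noncentral-t, approximations; tests show agreement with Monte-Carlo
simulation within ±2 points at practical sizes, and the two
parameterizations coincide at a matched correlation. One-sided is the
default (the convention for directional replication of known loci);
two-sided is a flag.

## The synthetic cohort

The generator emulates the statistical structure of a cross-sectional
adult population sample of n = 1578 with 31 independent biallelic loci:

- **Genotypes**: dosage ~ Binomial(2, f_i) per locus (HWE by
  construction), effect-allele frequencies drawn once per seed uniformly
  in [0.2, 0.8]; genotype missingness i.i.d. at 1.5% (matching per-assay
  call rates of ~98–99%).
- **Weights**: 31 fixed per-allele effects spread log-uniformly over
  [0.06, 0.40] kg/m² (the realistic GWAS range for BMI loci) and rescaled
  to mean 0.13 kg/m². Because the refitted per-allele score slope equals
  the mean generating weight by construction, this pins the recoverable
  effect at 0.13 kg/m² per allele exactly.
- **Covariates**: age ~ U(35, 74) years; gender ~ Bernoulli(0.5);
  physical activity 3-level (0.3/0.4/0.3); smoking 3-level
  (0.45/0.30/0.25 never/former/current); alcohol ~ Gamma(1.2, 8)
  units/week.
- **BMI**: intercept + Σ beta_i g_ij + linear covariate effects +
  Gaussian noise. The variance budget is solved analytically from the
  realized weight/frequency draw: with genetic variance
  G = Σ beta_i² · 2 f_i (1−f_i), covariate effects are scaled so their
  variance is 6G and the residual SD so total variance is 100G, fixing the
  score-alone, covariate and full-model R² at ~1%, ~6% and ~7%. The
  intercept places obesity (BMI ≥ 30) prevalence at 22.4%. A consequence
  of heterogeneous weights is a weighted-score SD of ~4.2 alleles and a
  total BMI SD of ~5.4 kg/m² (an equal-weight score with these frequencies
  would have SD ~3.7 and imply BMI SD ~4.8); the R², slope and prevalence
  anchors were kept in preference to the SD anchors, which are treated as
  soft references.
- **Glycaemia (pure mediation)**: log glucose, log insulin and HbA1c are
  linear in BMI plus noise (slopes 0.024 log-mmol/L, 0.05 log-μIU/mL and
  0.04 %-points per kg/m²; residual SDs 0.15, 0.35, 0.40), with an
  optional direct score effect that defaults to zero — so BMI adjustment
  removes the score-glycaemia association, the adjust-away signature.
  The glucose intercept places T2D (glucose ≥ 7.0 mmol/L) prevalence at
  9.2%. HOMA-IR = glucose·insulin/22.5 and HOMA-B = 20·insulin/(glucose −
  3.5) (the standard HOMA1 formulas); glucose ≤ 3.5 makes HOMA-B
  undefined and is recorded missing with a logged count. T2D uses only the
  glucose-threshold arm of the ADA definition (no treatment variable is
  simulated).

Everything is a deterministic function of (config, seed); each stage draws
from its own fixed-tag substream so stages are independently reproducible.

What the generator does **not** emulate: linkage disequilibrium between
loci (the score construction assumes independence anyway), gene–environment
interactions, non-Gaussian BMI skew, assortative or stratified population
structure, informative (non-random) genotype missingness, treated/diagnosed
diabetes, and measurement error in covariates. Passing tests therefore
demonstrate correctness of the machinery and calibration under the stated
model, not robustness of the scientific conclusions to these real-data
features.

## Numerical choices and degenerate inputs

Scores and fits are double precision with no storage rounding; report TSVs
are written at display precision alongside full-precision companions.
Rank-deficient designs are detected by SVD and reported with the implicated
columns; constant outcomes, single-class binary outcomes, all-missing
variants, nonpositive weight sums and strand-ambiguous variants without a
declared orientation are all hard errors. Frequency-based auto-flipping of
A/T and C/G variants is deliberately rejected: at ~31 loci the cost of an
explicit orientation declaration is trivial and silent mis-orientation is
not.

## Problem sizes in the test and acceptance runs

Replicate counts were chosen to make the stochastic checks statistically
decisive while keeping the default suite fast: 200 replicates of n = 1578
for CI coverage and R² calibration, 100 for the mediation rank test,
2000 draws for HWE type-I error, 5000–6000 vectorized replicates for the
power Monte-Carlo oracles, and 50 replicate cohorts pooled in the
acceptance script.
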