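# Methods

## The model

`bivarlmm` fits a stacked bivariate linear mixed model to two blood-pressure
traits (SBP and DBP, mmHg) measured repeatedly at irregular examination
times, and tests each SNP's additive effect on both traits jointly.  For
subject *i* with trait-*k* observations stacked into a single response,

```
Y_i = X_i beta + Z_i gamma_i + W_i + eps_i
```

* `X_i` is block-structured: every fixed effect (intercept, genotype
  dosage, examination time in years since enrollment, baseline age, sex,
  antihypertensive medication use, smoking status) gets a separate
  coefficient per trait.  This is the standard "interact every regressor
  with a trait indicator" coding for stacked multivariate responses.
* `gamma_i ~ N(0, G)` are subject-level random intercepts and time slopes
  per trait; `G` is unstructured 4x4 (UN), so the two traits' intercepts
  and slopes can covary freely.  This is the channel through which
  cross-trait correlation enters the default model.
* `eps_i` is iid within trait with trait-specific variances
  (`Sigma = diag(sigma_e1^2, sigma_e2^2) (x) I` on the observed rows).
* `W_i` is an optional serial process.  Two families are available beyond
  the default `UN_RE` (no serial term):
  * `UN_RE_OU`: a bivariate Ornstein-Uhlenbeck process with stationary
    covariance `C` (2x2 PSD) and covariance
    `R_i(s,t) = C * exp(-lam_bar (t-s))` elementwise, where the diagonal
    entries decay at trait-specific rates `lam_k > 0` and the cross entry
    at the average rate `(lam_1 + lam_2)/2`.  This is a deliberate
    narrowing of the general matrix-exponential OU form `C e^{B(t-s)}`:
    with an arbitrary `B` the process is not identifiable at cohorts of
    ~140 subjects and 3 visits, while the diagonal-decay restriction
    guarantees symmetry and positive semidefiniteness.  Traits are
    serially independent iff the off-diagonal of `C` is zero.
  * `AR1_VISIT`: per-trait AR(1) on the *visit index*, retained only so the
    UN-vs-AR(1) AIC comparison can be reproduced.  It assumes equally
    spaced visits, which irregular 1.4-7.6-year gaps violate — the reason
    the UN family is the shipped default.

Estimation is by REML.  The objective, with `V_i = Z_i G Z_i' + R_i +
Sigma_i` and `r_i` the GLS residuals at the profiled beta-hat, is

```
l_R = -1/2 [ (N - p) log 2pi + sum_i log|V_i|
             + log|sum_i X_i' V_i^{-1} X_i| + sum_i r_i' V_i^{-1} r_i ]
```

(the `(N - p) log 2pi` constant is included so the value matches the dense
multivariate-normal formula exactly).  Variance parameters are optimized
unconstrained — log-Cholesky for `G` and `C`, log for residual variances
and OU decay rates, atanh for AR(1) correlations — by L-BFGS-B with an
analytic gradient for the `UN_RE` family (finite differences for the serial
families).  Defaults: gradient tolerance 1e-7, relative function tolerance
1e-10, iteration cap 500, method-of-moments starting values from per-trait
OLS residuals.  Non-convergence is flagged, never silently ignored;
near-singular `G` estimates are flagged as boundary solutions.  Setting
`cross_trait_random=False` zeroes the cross-trait Cholesky block, which
constrains `G` block-diagonal and makes the bivariate likelihood factor
exactly into the two univariate ones — the basis of a structural self-test.

`AIC = -2 l_R + 2 (number of free covariance parameters)` — the REML
convention that counts covariance parameters only, so AIC comparisons
across covariance families at a fixed mean structure are meaningful.

## The joint test

For each SNP the 2-df Wald statistic is `W = beta_G' S^{-1} beta_G` with
`beta_G = (beta_SBP, beta_DBP)` and `S` its 2x2 covariance from
`(sum_i X_i' V_i^{-1} X_i)^{-1}`.  Both reference distributions are always
reported side by side: the large-sample chi-square with 2 df, and
`F(2, df2)` on `W/2`.  Since an F tail with finite denominator df is heavier
than the corresponding chi-square tail, `p_chi2 <= p_F` everywhere; the
scan's headline p-value is the F-based one.

The denominator df is policy-based, because no finite-sample df is exact
for this model:

* `residual`: `N_obs - rank(X)`;
* `containment` (default): `N_obs - rank(X) - sum_i rank(Z_i)`.

On the complete 141-subject, 3-exam, 2-trait design with a 12-column X and
a shared 2-column per-subject random-effect design
(`random_effects_shared=True`, the SAS-style "subject + time" coding), the
containment count is 846 - 12 - 282 = 552.  With the default trait-specific
4-column Z it is 846 - 14 - 564 = 268.  The df used is reported in every
scan row so consumers can audit it.

## Genotype QC

Subjects are filtered by genotyping call rate (>= 0.95) first; SNP
statistics are then computed on retained subjects: call rate >= 0.95,
sample MAF >= 0.05 (dosages re-oriented to the sample-minor allele when the
nominal minor allele exceeds 0.5, with the flip recorded), and the
Levene-Haldane exact Hardy-Weinberg test with p >= 1e-3.  The HWE test
conditions on allele counts and sums the probabilities of all heterozygote
counts at most as probable as the observed one (standard tail, no mid-p);
monomorphic SNPs get p = 1 but fail the MAF filter, so they are never
excluded *for* HWE.  Whether HWE should be computed before or after the
subject filter is ambiguous in general; this package computes it after,
and the ordering is documented rather than configurable-by-accident.

## The synthetic cohort generator

`SimulationConfig` generates cohorts with the structure the analysis
assumes: `n_subjects` (default 141) unrelated subjects, `n_exams` (default
3) examinations with exam 1 at time 0 and later exams at cumulative
Uniform(1.4, 7.6)-year gaps, baseline age Uniform(20.3, 94.2) years, sex
Bernoulli(0.5), medication and smoking as subject-level Bernoulli states
(initial probabilities 0.3 / 0.2) with a 0.1 per-visit switch probability,
genotypes Binomial(2, MAF) (exact HWE in expectation; default MAF 0.30, one
causal SNP per cohort, extra SNPs null), phenotypes from the model above,
and missingness options: visit-level MCAR (`miss_visit_prob`) and
last-exam dropout (`drop_last_exam`, affecting 97/141 of subjects) —
MCAR suffices because the analysis uses available-case deletion.

Default effect sizes and variance components are calibrated to a mid-range
power regime at n = 141:

* SNP effects beta = (-1.4951, -2.3810) mmHg per minor-allele copy;
* `G` intercept variances 13 / 34 mmHg^2 with cross-trait intercept
  correlation 0.5, slope SDs 0.30 / 0.25 mmHg/yr, slope covariances 0;
* residual SDs 7.04 / 11.53 mmHg.

These give per-trait standardized SNP effects near 2.0 (univariate power
roughly 45-55% at alpha = 0.05) and an effective correlation between the
two coefficient estimates near 0.21 after residual dilution of the
G-level 0.5 — a regime in which the 2-df joint test is clearly more
powerful than either 1-df test (noncentral chi-square arithmetic predicts
roughly a 13-point power gap over the better univariate test).  The DBP
variance exceeds the SBP variance under these defaults — backwards
relative to typical clinic measurements — because the larger DBP effect
size must be scaled to a comparable standardized effect; the generator is
a testbed for the statistics, not a physiological simulator.  Other things
real cohorts have that the generator does not: pedigree relatedness,
linkage disequilibrium between SNPs, population structure,
informative (non-MCAR) dropout, and medication effects that depend on the
latent phenotype.  Passing tests therefore validate the estimator and test
calibration under the model's own assumptions, not robustness to these
violations.

## The power study

`estimate_power` simulates `n_replicates` (default 200) cohorts; on each it
runs the bivariate fit + 2-df joint test and both univariate fits + 1-df
tests on the same data, and tallies rejections at alpha = 0.05 and the
genome-wide 7.2e-8.  Replicate seeds derive deterministically from the
master seed; replicates whose fit fails are recorded, excluded from that
method's denominator, and reported — never resampled, since resampling
conditional on convergence biases power.  Power differences between
methods are assessed with the *paired* Monte Carlo standard error (the
methods share replicates, so the paired SE is the correct uncertainty for
the difference).  Wilson 95% confidence intervals accompany every
proportion.

## Numerical choices and problem sizes

* Marginal covariances are assembled and factorized in batches of subjects
  sharing a row count, so a 141-subject fit costs a few hundred
  6x6 Cholesky factorizations per objective evaluation.
* The genomic inflation factor is the median-based lambda_GC computed by
  converting p-values (whatever their originating test) to 1-df chi-square
  quantiles and dividing the median by 0.45494.
* Degenerate covariances encountered during optimization are treated as a
  large penalty rather than an error, so the optimizer backs away from the
  boundary instead of aborting.
* Test-suite problem sizes are chosen so the whole suite runs in minutes on
  one core: parameter recovery uses 50 replicates of 500 subjects, type-I
  calibration 1000 replicates of 141 subjects, power ordering 200
  replicates, and oracle comparisons use 8-10-subject instances where
  dense-matrix formulas and derivative-free global search are exact
  references.

## Known limitations

* No kinship/pedigree random effects: the model assumes unrelated
  subjects.
* The general OU cross-decay matrix `B` is intentionally restricted
  (diagonal decay); serial-family gradients are numerical, so those fits
  are slower and coarser than the default family's.
* The containment df is a counting convention, not an exact small-sample
  distribution; with correlated data the F test is approximate (the type-I
  calibration shows it runs slightly conservative relative to chi-square).
* Scan-level multiplicity handling is a fixed threshold (7.2e-8 by
  default); no FDR machinery is provided.
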