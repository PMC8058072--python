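# Methods

## The study design being modeled

The pipeline reproduces a two-stage diagnostic-biomarker qualification
design for urinary miRNAs. A pool of enrolled healthy controls and cancer
cases is reduced to an age/sex-comparable analysis cohort by propensity
matching; urine samples with poor RNA quality are removed; a small
discovery arm identifies candidate markers by differential screening; and a
larger training/test arm qualifies each candidate by cross-validated ROC
analysis of its normalized expression. Each stage is available on its own
(library functions and CLI subcommands) and composed end to end by
`run_pipeline` / `DiagnosticStudy`.

## Synthetic cohorts

### Noise model

Ct (threshold-cycle) values are Gaussian in the cycle domain. Since
relative expression is `2^-ΔCt`, the cycle domain *is* the log2-expression
scale: a marker simulated with case shift `δ` cycles (cases lower Ct) has
true fold change `2^δ` and true single-marker AUC

    A = Φ(δ / (σ√2)),

the binormal closed form for two Gaussian groups with common SD `σ`. The
generator exposes `shift_for_auc(A, σ)` so that effect sizes can be stated
on the AUC scale; the default marker panel back-solves its shifts from
target training-set AUCs of 0.79/0.79/0.69/0.64/0.62 for the five active
markers (σ = 1 cycle), with three null markers alongside. This closed form
is also the independent oracle for the calibration tests.

### What the generator emulates, and defaults

- Group sizes: 299 controls / 44 cases enrolled (the consort flow of the
  emulated study), reduced by matching and quality exclusion to ≈150/43.
- Age and sex drawn from a shared distribution for both groups (truncated
  normal, mean 68, SD 7.5 years, within the 20–90 enrollment window; 10%
  female), i.e. balanced by design since the emulated cohort is
  post-matching. `case_age_shift` deliberately unbalances ages to exercise
  the matching stage.
- Serum creatinine log-normal with median 0.84 mg/dl.
- TNM stage I–IV for cases with probabilities (16, 4, 12, 11)/43 and
  T stage (21, 1, 10, 11)/43, the case-mix frequencies of the emulated
  cohort.
- Two internal-control assays with between-sample SD 0.3 cycles versus
  1.0 cycle for markers.
- Duplicate reactions: replicate 2 = replicate 1 + N(0, 0.15²) cycles,
  typical qPCR technical error.
- Poor-quality rate 0.094 (≈20 exclusions out of ≈213, matching the
  emulated consort flow).
- Stage correlation: the designated marker (default the miR-4327 analogue,
  ρ = −0.435) is coupled to an ordinal stage variable by a Gaussian copula:
  the marker's Ct noise and the latent stage normal share correlation
  `r = 2 sin(π(−ρ)/6)` (the bivariate-normal Spearman inversion; the sign
  flips because expression decreases in Ct). Discretizing the latent into
  four stages attenuates the realized Spearman slightly; the generator
  targets ρ within ±0.1 at n ≥ 200, which the tests verify.

### What it does not emulate

No microarray intensity domain (screening operates on Ct/expression), no
inter-assay efficiency differences, no hemolysis/collection-time artifacts,
no per-assay dropout inside good-quality samples (undetermined values
outside the quality-failure path must be supplied by the caller). Passing
tests therefore demonstrate correctness of the statistical machinery under
a clean log-normal expression model, not robustness to every failure mode
of real urinary qPCR data.

A per-sample global Ct offset (`sample_loading_sd`, default 0) models urine
concentration differences; it is off by default so that the generator's
stability contract for internal-control assays holds on raw Ct, and because
`2^-ΔCt` removes any such offset exactly (the shift-invariance tests cover
this identity directly).

## Propensity matching

Maximum-likelihood logistic regression of case status on age and a single
male indicator (statsmodels). Constant covariates are dropped with a
warning; on (quasi-)complete separation — detected by non-convergence or
exploding coefficients — a ridge-penalized fit (`α = 10⁻³`) is substituted
and flagged. The C-statistic is the rank-based AUC of the fitted scores, so
it is invariant to any monotone transform of the score.

Matching is greedy 1:ratio nearest neighbor on the logit scale: cases are
visited in seeded random order, each taking its nearest remaining controls
within the caliper (0.2 × pooled-sample SD of the logit by default; a
within-group-average SD option exists). Without replacement by default;
distance ties break by subject id so runs are exactly reproducible.
Standardized differences are reported as absolute values, `|m₁−m₂| /
√((s₁²+s₂²)/2)` for continuous and the analogous proportion form for binary
covariates; zero pooled variance with unequal means yields `inf` rather
than an exception.

One deliberate deviation from conventions stated elsewhere: the 6-subject
all-separated toy sometimes used to illustrate logistic fitting has no
finite MLE, so the coefficient-recovery test uses an overlapping-age toy
against a direct numerical likelihood maximization, and the separated input
instead exercises the penalized fallback (C-statistic → 1).

## Normalization

Per-cell Ct is the arithmetic mean of finite replicates; a replicate range
above `discordance_limit` (default 1.0 cycle — a documented convention, not
a claim about any particular laboratory's practice) flags the cell without
dropping it. Internal controls are the `n` assays minimizing the
across-sample SD of (Ct − per-sample global mean Ct); an assay tracking the
global mean up to a constant offset scores exactly 0, making the criterion
shift-invariant. Reference aggregation is the arithmetic mean of Ct across
the chosen controls (geometric mean of expression), standard ΔCt practice
with two references. Undetermined Ct is missing data and is never imputed;
samples lacking a finite reference Ct are excluded and listed. Report
tables scale `2^-ΔCt` by 100 (the "×10⁻²" convention); stored values stay
unscaled.

## Screening

Fold change is the ratio of group means of relative expression (a `center`
switch selects medians); the p-value is the two-sided Mann–Whitney test; a
marker is selected when `FC > 2` or `FC < 0.5` and `p < 0.05`. No
multiple-testing correction is applied at this stage — the design
deliberately uses a permissive discovery screen that the training/test
stage must confirm. Stability is operationalized as the fraction of samples
with finite expression, threshold 0.8 by default.

At the emulated study's discovery size (6 controls vs 3 cases) the smallest
attainable exact two-sided Mann–Whitney p is 2/84 ≈ 0.024, so even strong
markers pass the screen only stochastically; the end-to-end validation
tests therefore use discovery splits sized for screening power (60/30)
while the default configuration keeps the study's 6/3 split. This fragility
of tiny discovery cohorts is a property of the design itself, faithfully
reproduced.

## Evaluation statistics

- **Mann–Whitney.** Midranks throughout. For `n₁+n₂ ≤ 12` the two-sided p
  is computed by full enumeration of all `C(n, n₁)` group assignments,
  summing both tails via `|U − n₁n₂/2|` (the permutation null of U is
  symmetric about its mean even with ties); larger samples use the normal
  approximation with tie and continuity corrections.
- **ROC/AUC.** `AUC = (#[case > control] + ½#[case = control])/(n₁n₂)`,
  identical to `U/(n₁n₂)`; a property test holds this identity to 1e−12.
- **Optimal cutoff.** Youden's J maximized over midpoints between adjacent
  distinct pooled scores plus the two degenerate extremes; classification
  rule `score ≥ cutoff ⇒ case` (higher expression indicates disease). Ties
  in J break toward higher sensitivity, then the lower cutoff; with all
  scores equal this returns the everything-case cutoff (sens 1, spec 0).
- **Cross-validation.** Folds are label-stratified and seeded
  (unstratified folds would risk single-class test sets with ~40 cases in
  5 folds). Within each fold the marker score itself is evaluated by ROC on
  the train and test portions — single-marker scores need no fitted
  classifier, so "training" AUC is the resubstitution AUC of the 4/5
  portion. The reported AUC is the arithmetic mean over folds.
- **Bootstrap.** Percentile intervals from seeded, group-stratified
  resamples; endpoints use the (B+1)p order-statistic convention (Weibull
  quantiles), the classical percentile-interval positioning, which is
  better calibrated than interpolation type 7 at modest B. Resamples on
  which the statistic is undefined are redrawn and counted. For the CV mean
  AUC, subjects are resampled within class and the full k-fold procedure is
  rerun per resample (B = 1000 by default; `n_boot=0` skips CIs in
  Monte-Carlo studies). A Hanley–McNeil analytic AUC interval is available
  for comparison.
- **Categorical tests.** Fisher's exact two-sided p (sum of hypergeometric
  probabilities not exceeding the observed table's) unless every expected
  count exceeds 5, then Pearson chi-square; the rule applied is recorded.
  The boundary (expected counts exactly 5) goes to the exact test.
- **Spearman.** Pearson correlation of midranks with the t-approximation
  p-value; zero rank variance is an error, not a silent NaN.

Single-cohort ROC CIs use the same stratified percentile bootstrap as the
CV stage (2000 resamples) — one method everywhere rather than mixing
analytic and resampling intervals. Stage-I analyses reuse the full control
group against stage-I cases only, and report both a stage-I-specific Youden
cutoff and the stage-I sensitivity at the all-stage cutoff, since either
convention is defensible.

## Orchestration and reproducibility

Stage order: simulate/load → match → quality exclusion → discovery split →
normalize (replicates → internal controls → ΔCt, computed once on the whole
retained cohort) → screen (discovery arm) → evaluate (training/test arm,
all-stage and stage-I strata, stage correlation per qualified marker) →
results document. Each stage's seed derives from the root seed as
`crc32(stage_name) XOR root (mod 2³¹)`, so stages can be rerun
independently and identical config + seed gives byte-identical JSON output.
Any stage failure aborts with the stage name and a machine-readable error
code.

## Problem sizes used in validation

Monte-Carlo suites use: 200 cohorts for the null-AUC distribution, 10
cohorts of n = 2000/group for closed-form AUC convergence (mean across
cohorts, isolating the expectation from the ±0.008 single-cohort sampling
noise), 500 discovery-size replicates for screening power, 100 seeds at
n = 144/40 for CV recovery of a 0.79-AUC marker, 1000 null markers for
type-I calibration, 500 replications at B = 200 for bootstrap coverage, and
50 end-to-end pipeline replicates per ground-truth scenario. These sizes
keep every check's Monte-Carlo error comfortably inside its stated
tolerance.

## Known limitations

- The discovery screen's behavior at n = 9 is dominated by the discreteness
  of exact rank tests; results at that size should be read as "can detect
  only near-perfect separation".
- The penalized separation fallback reports finite but regularized
  coefficients; their scale depends on the ridge strength and should not be
  interpreted as effect estimates.
- The bootstrap CI for the CV mean AUC treats fold reassignment as part of
  the resampled procedure; it quantifies subject-sampling plus fold-split
  variability jointly, not subject sampling alone.
- Expression values are simulated exactly log-normal; heavy-tailed or
  zero-inflated real data may degrade the screen's calibration in ways the
  test suite does not measure.
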