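# Methods

`acnadi` implements a race-stratified risk-prediction analysis for advanced
colorectal neoplasia (ACN) in a screening-colonoscopy population, with a
neighbourhood-deprivation augmentation stage.  Because the underlying
patient data are not public, the package pairs every estimator with a
synthetic multilevel cohort generator whose defaults encode the published
study conditions, so that every downstream quantity is recovery-testable.

## The synthetic cohort generator

**Census tracts.**  Each of `n_tracts` (default 598) tracts carries 17
socioeconomic indicators generated from a single-factor model

    x_k = lambda * f + sqrt(1 - lambda^2) * eps_k,   f, eps_k ~ N(0, 1),

with a common loading `lambda` across indicators.  The indicator
correlation matrix is then equicorrelated with off-diagonal `lambda^2`,
whose leading eigenvalue is `1 + 16 lambda^2`; the default loading is set
from the identity share = (1 + 16 lambda^2)/17 so the first principal
component carries 60.2% of total indicator variance.  Indicators are
abstract standardized columns; `v1` is designated the poverty-rate proxy
and anchors the orientation of the deprivation index.

**Subjects.**  Two strata are generated by default — European-American
(EA, n = 1457) and African-American (AA, n = 936) — nested in the same
tract table.  Stratum-level covariate distributions (age, BMI, smoking
years, red-meat and alcohol frequency; proportions of female sex,
first-degree family history of colorectal cancer, diabetes, calcium use)
default to the published cohort characteristics.  Continuous covariates
are truncated normals (age restricted to the 50–80 screening-eligibility
window, BMI to 15–60, the remaining quantities floored at 0); the
pre-truncation location is solved numerically so the *realized* mean of
the truncated distribution equals the configured mean, since the published
moments describe the eligible population.  Realized SDs are therefore
slightly below the configured values for strongly truncated quantities
(for example smoking years); means are exact in expectation.

**Tract assignment.**  Each subject draws a target deprivation level from
a truncated normal on [0, 100] with the stratum's ADI mean and SD (EA
28.1/11.5; AA 53.1/15.3) and is assigned to the tract with the nearest
ADI score.  With 598 tracts spanning [0, 100] this reproduces both the
stratum ADI means and SDs (a one-parameter weighting over deprivation
ranks could match only the mean), and yields the >25-unit separation
between strata seen in the source population.

**Outcomes.**  ACN status is Bernoulli with

    logit p = alpha_race + sum_k beta_k x_k + beta_ADI * (ADI / 10) + u_tract,
    u_tract ~ N(0, tract_sigma^2),

i.e. the same augmented-model form the estimation stage assumes.  The
covariate log-odds default to the published multivariable odds ratios
(e.g. male 1.41, per year of age 1.03, per kg/m² 1.03, family history
1.69, diabetes 1.49, calcium 0.59; alcohol is a forced candidate with no
true effect).  The deprivation effect per 10 ADI units defaults to 1.24
in the EA stratum and 1.07 in the AA stratum.  `tract_sigma`, the
residual tract heterogeneity on the logit scale, is not identifiable from
the published numbers; its default 0.3 gives modest, nonzero cluster
variance and — combined with the default deprivation effects — implies a
true ADI share of tract-level linear-predictor variance of ~40% (EA) and
~11% (AA), close to the published variance partitions.
`tract_sigma_for_adi_share` inverts share = Var_ADI/(Var_ADI + sigma²)
exactly when a specific share is required.  The stratum intercept
`alpha_race` is calibrated by bisection so the expected prevalence over
the realized linear predictors equals the stratum target (6.3% EA, 8.4%
AA; jointly 7.1%).

All randomness flows from one master seed through per-stage child streams
(tract indicators, tract effects, assignment, covariates, outcomes) with
fixed spawn indices, so equal configurations give byte-identical tables.

**What the generator does not emulate.**  Real covariates are correlated
(e.g. smoking with alcohol), zero-inflated (smoking years), and associated
with neighbourhood deprivation; here covariates are mutually independent
and independent of ADI within stratum.  Real deprivation effects need not
be log-linear in ADI, and real tract effects need not be Gaussian or
shared across strata.  Passing recovery tests therefore demonstrate that
the estimators are correct under the stated model, not that the model is
correct for any real population.

## Area Deprivation Index

The ADI is the first principal component of the 17 indicators, computed on
the correlation matrix (indicators have heterogeneous units; standardizing
each column to mean 0/SD 1 makes the index invariant to affine changes of
any indicator).  The eigenvector is oriented so the poverty proxy loads
positively — deprivation increases the score — and tract scores are
min–max scaled to [0, 100].  Percentile-rank scaling is available as an
option (`scaling="percentile"`), since national deprivation indices are
often published as percentiles; min–max is the default.  A leading
eigenvalue tie within 1e-12 is resolved by a deterministic sign rule and
flagged.

## Logistic regression core

Maximum likelihood is computed by iteratively reweighted least squares
with step-halving, so the log-likelihood is non-decreasing across
iterations; convergence is declared when the largest score component falls
below 1e-8 or the relative log-likelihood change falls below 1e-10 (at
most 100 iterations).  Rank-deficient designs raise an error naming the
first aliased column.  A coefficient exceeding 10 in absolute value while
the likelihood is still improving sets a separation flag.  Wald tests use
the normal reference, two-sided.  Nagelkerke's pseudo-R² rescales the
Cox–Snell R² by its attainable maximum.

Backward elimination refits the model after every removal (rather than
using the one-shot Wald approximation): the non-forced term with the
largest Wald P above the threshold (default 0.10) is removed, ties broken
lexicographically by term name so the result is invariant to column order.
Forced terms are never removed.

The LASSO redundancy check maximizes the penalized likelihood by
coordinate descent on the IRLS quadratic approximation, with standardized
covariates and an unpenalized intercept.  The penalty grid descends three
decades from `lambda_max` (the smallest penalty with an all-zero
solution); the reported solution maximizes mean held-out AUC over
stratified 3-fold cross-validation, ties resolved toward the larger
penalty.  The solver agrees with scikit-learn's saga L1 solver to ~1e-10
(used as a test oracle only).

## Stability selection

Candidates are risk factors with univariate association P < 0.10 (Pearson
chi-square for binaries, Welch t for continuous covariates) united with
six literature-established forced candidates (sex, BMI, alcohol, smoking,
first-degree family history, red meat).  Each of B = 1000 bootstrap
resamples refits the full candidate model and runs backward elimination;
survivors are counted.  Resamples whose fit degenerates (single outcome
class, collinear resample, separation) are redrawn so B effective
replicates always contribute; more than 20% failures aborts.  Final
predictors are those with selection frequency > 0.4, optionally extended
by the frequency-drop rule: among consecutive gaps in the ordered
frequency plot *below* the threshold, the largest drop (first on ties) is
located and all terms above it are retained.  A flat plateau never
extends the set.  In the combined-population model, race is forced into
the final model even if unselected.

## Random-intercept logistic regression (AGQ)

The marginal likelihood integrates a Gaussian random intercept per census
tract out of the Bernoulli likelihood.  Each cluster's integrand is
re-centred at its posterior mode (vectorised damped Newton; strictly
concave inner problem) and re-scaled by the mode curvature before applying
Gauss–Hermite quadrature with 10 nodes by default — quadrature error is
below 1e-10 at the default cluster sizes, and 10 vs 30 nodes agree to
1e-4 on simulated data.  The outer problem maximizes over the fixed
effects and the log of the random-effect SD (enforcing positivity) with
L-BFGS-B and central-difference derivatives; standard errors come from
the numeric Hessian at the optimum.  Fits that run to the variance lower
bound are reported as zero tract variance with a boundary flag.  The
implementation matches lme4's `glmer(..., nAGQ=10)` to ~1e-4 in
log-likelihood and ~2e-3 in estimates on common data (test oracle only).

A caution established during validation: with ~2.4 subjects per tract and
~7% prevalence — the study's own geometry — the ML estimate of the tract
SD is barely identified.  Its sampling distribution piles mass at zero and
carries a long right tail, and single-dataset estimates as far from truth
as 0 or 2× truth are routine (lme4 reproduces the same estimates, so this
is the estimator, not the optimizer).  All variance-based summaries in
this package are therefore reported either per fit with that caveat or
pooled across replicate cohorts.

## ADI augmentation, LRT and variance partition

The two-stage augmentation fits

    acn ~ intercept + (base predicted risk)/0.1 + ADI/10 + (1 | tract)

with the base prediction entering on the absolute-probability scale, so
the two odds ratios are per 0.1 of predicted risk and per 10 ADI units.
Each predictor's P value comes from a likelihood-ratio test against the
nested model without it (chi-square reference; the tested terms are fixed
effects, so no boundary correction applies).  If the optimizer leaves the
full model below a nested null, the full fit is restarted from the null
optimum; a persistent inversion raises an optimization-failure error.
Wald confidence intervals are reported.

The variance partition (Var_Null − Var_Full)/Var_Null compares the tract
variance of the augmented model with the model omitting ADI.  It can be
negative in finite samples and is then returned raw with a warning.
Because single-fit tract variances are so dispersed (above), the recovery
experiments estimate the partition from variances averaged over 100
replicate cohorts; repeat runs of that pooled estimator land within
~±2 percentage points of each other, against generating shares of 38.7%
(EA) and 10.6% (AA).  The pooled AA estimate centres near 6% rather than
10.6% because the boundary-censored, long-tailed Var_Null estimates
inflate the pooled denominator while the small true ADI contribution is
fixed — a finite-sample property of the ML variance estimator at these
cluster sizes, not an implementation artefact.

## Evaluation

Discrimination is the C-statistic (tie-aware Mann–Whitney form, identical
to exhaustive pair counting), with a percentile bootstrap CI from 2000
resamples of subjects scored by the frozen model; single-class resamples
are redrawn.  Calibration is the Hosmer–Lemeshow statistic
H = Σ (O−E)²/(E(1−E/n)) with df = G − 2 under both grouping schemes:
deciles of predicted risk (tied cut points merged, df adjusted) and
explicit groups such as ADI quartiles.  Prevalence trends across ordered
deprivation groups use the Cochran–Armitage test with equally spaced
scores.  Cross-application re-scores a serialized model on another
population stratum with the same metrics.

## Pipeline and problem sizes

The `run` pipeline executes, per population (combined with race forced,
EA-only, AA-only): screening → 1000-replicate stability selection → final
fit → LASSO redundancy check → evaluation on the development population
and the complementary stratum → ADI augmentation with LRT and variance
partition → calibration across ADI quartiles before and after
augmentation.  Reports are emitted as JSON and aligned text and are
byte-identical under a fixed seed.

The test suite and the reproduction script scale replication to the
quantity at hand: 20 replicate cohorts for the deprivation odds ratio
(its per-cohort estimate is well-behaved), 100 for the variance
partitions (heavy-tailed per-cohort estimates), single cohorts for
distributional checks, and reduced cohort sizes only where the property
under test is size-free (e.g. permutation size of the LRT).

## Known limitations

- Single cluster level only; no crossed/nested structures, random slopes,
  or non-Gaussian random effects.
- Continuous covariates enter untransformed (the per-unit odds ratios
  assume log-linearity); no splines or interactions.
- No Firth correction: separated bootstrap resamples are redrawn rather
  than penalized.
- The HL statistic's chi-square reference with df = G − 2 is the
  development-data convention; no external-validation df adjustment.
- Percentile vs min–max ADI scaling changes individual scores (not the
  index ordering); results are reported under min–max scaling.
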