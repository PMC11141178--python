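# acnadi

Race-stratified risk prediction for **advanced colorectal neoplasia (ACN)**
— colorectal cancer plus advanced precancerous adenoma — with a
**neighbourhood-deprivation augmentation** stage, built for
biostatisticians studying how area-level socioeconomic context shapes
clinical risk models.

Screening-colonoscopy cohorts cluster geographically: subjects live in
census tracts whose socioeconomic deprivation is itself a risk factor, and
a risk model fitted only on individual covariates miscalibrates across
neighbourhoods — overestimating risk in affluent tracts and
underestimating it in deprived ones.  `acnadi` implements the full
analysis that quantifies and repairs this:

1. **Synthetic multilevel cohort generator** — two race strata
   (European-American n=1457, African-American n=936) nested in 598 census
   tracts, with covariate distributions, effect sizes, outcome prevalences
   (6.3% / 8.4%) and race-specific deprivation distributions defaulting to
   the study conditions the package targets.  Outcomes follow
   `logit p = α + Σ βₖxₖ + β_ADI·(ADI/10) + u_tract`,
   `u_tract ~ N(0, σ²)`.
2. **Area Deprivation Index (ADI)** — first principal component of 17
   tract-level socioeconomic indicators (correlation-matrix PCA), oriented
   so the poverty proxy loads positively, scaled to [0, 100].
3. **Logistic regression core, from first principles** — IRLS with
   step-halving, Wald tests, backward elimination at P > 0.10, Nagelkerke
   R², and a coordinate-descent LASSO with 3-fold CV on AUC as a
   redundancy check.
4. **Bootstrap stability selection** — univariate screening (P < 0.10)
   plus forced literature candidates, 1000 bootstrap resamples each
   followed by backward elimination, selection-frequency accounting, and
   the final rule: frequency > 0.4 and/or above the largest drop in the
   ordered frequency plot.
5. **Random-intercept logistic mixed models by adaptive Gauss–Hermite
   quadrature (10 nodes)** — the two-stage augmentation
   `acn ~ predicted_risk/0.1 + ADI/10 + (1|tract)`, likelihood-ratio
   tests, and the tract-variance partition
   `(Var_Null − Var_Full)/Var_Null`.
6. **Evaluation** — C-statistic with a 2000-resample bootstrap CI,
   Hosmer–Lemeshow calibration over risk deciles and over ADI quartiles,
   Cochran–Armitage prevalence trend, and cross-application of any
   serialized model to another population stratum.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the whole analysis on a synthetic cohort (reduced bootstrap sizes for
a quick demonstration; defaults are 1000/2000):

```bash
acnadi run --seed 1 --b-stability 200 --b-cstat 500 --out demo
```

The text report (`demo/report.txt`) from this exact command:

```
ACN risk-prediction analysis report
========================================
All: n=2393 events=149 prevalence=6.2% ADI=37.8 (17.5)
AA: n=936 events=60 prevalence=6.4% ADI=52.6 (15.0)
EA: n=1457 events=89 prevalence=6.1% ADI=28.2 (11.1)
...
Population EA
----------------------------------------
  final predictors: bmi, smoking_years
  Nagelkerke R2: 1.2%
  C-statistic 0.580 (0.519-0.642), HL P=0.313
  ADI OR/10 1.48 (1.20-1.82), LRT P=0.000
  ADI share of tract variance: 53.1%
  calibration across ADI quartiles: P=0.001 before, P=0.339 after augmentation
```

Reading the EA block: the base risk model (selected by stability
selection) discriminates modestly (C = 0.580); across ADI quartiles it is
clearly miscalibrated (Hosmer–Lemeshow P = 0.001) because the generating
process contains a real deprivation effect the base model omits.  Adding
ADI in the tract mixed model estimates an odds ratio of 1.48 per 10 ADI
units on this single cohort (the generating value is 1.24; single-cohort
estimates carry this much noise at 89 events) and repairs the calibration
(P = 0.339 after augmentation).  Single-run tract-variance shares are
heavily dispersed at ~2.4 subjects per tract — the recovery experiments
below pool them across replicate cohorts.

The same stages are available piecewise (`acnadi simulate`, `adi`,
`select`, `fit`, `evaluate`, `augment`, `write-config`), and as library
functions:

```python
from acnadi import ea_like_config, generate_cohort, fit_logistic, augment_with_adi
from acnadi.io import model_frame

tracts, cohort = generate_cohort(ea_like_config(seed=1))
X = model_frame(cohort)
base = fit_logistic(X[["male", "age", "bmi", "family_history_fdr",
                       "smoking_years", "calcium_use"]], cohort["acn"])
aug = augment_with_adi(base.predict(X), cohort["adi"], cohort["acn"],
                       cohort["tract_id"])
print(aug.or_adi_per_10, aug.lrt_p_adi, aug.adi_variance_share)
```

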