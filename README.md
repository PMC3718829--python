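# strokemarker

Does a blood biomarker add prognostic value over the clinical information a
stroke physician already has? `strokemarker` implements the full statistical
pipeline for answering that question for a continuous plasma biomarker
(midregional pro-adrenomedullin, MR-proADM, nmol/l) and the 90-day functional
outcome after acute ischemic stroke, dichotomized on the modified Rankin
Scale into favourable (mRS 0–2) and unfavourable (mRS 3–6):

* **Logistic prognostic models.** Model 1 regresses the unfavourable outcome
  on age, admission NIHSS and recanalization therapy; model 2 adds the
  biomarker. Fits are maximum likelihood (IRLS) with Wald 95% confidence
  intervals on the odds ratios, optional backwards elimination, and explicit
  separation/collinearity errors.
* **Discrimination.** AUC by the midrank (Mann–Whitney) formula and DeLong's
  nonparametric test for two correlated AUCs, built from placement values:
  for an event, the proportion of non-events scored below it (ties half);
  the mean placement value is the AUC, and the empirical covariance of paired
  placement values gives the variance of the AUC difference.
* **Reclassification.** Category-free NRI between nested-model risks
  (NRI = [P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)],
  z = NRI / √((up_e+down_e)/n_e² + (up_ne+down_ne)/n_ne²)), and the
  categorical NRI for the SPAN-100 + biomarker-quintile rule: SPAN-100
  (age + NIHSS, positive if > 100) predicts the outcome; SPAN-negative
  patients in the upper three biomarker quintiles are reclassified upward,
  SPAN-positive patients in the lower two quintiles downward.
* **Survival.** Kaplan–Meier curves by biomarker quintile with Greenwood
  variances, and the k-group log-rank test plus its 1-df ordered-trend
  variant (scores 1..k).
* **Synthetic cohorts.** A calibrated generator (Gaussian copula over age,
  NIHSS and the log-normal biomarker; logistic outcome model; quintile-graded
  death mechanism) reproduces the summary structure of a 168-patient stroke
  cohort so the whole pipeline is testable without patient data.

## Worked example

Published reclassification counts can be checked directly, with no cohort
file (events: 36 reclassified up, 8 down, of 89; non-events: 11 up, 0 down,
of 79):

```bash
strokemarker nri-table --events-up 36 --events-down 8 --n-events 89 \
    --nonevents-up 11 --nonevents-down 0 --n-nonevents 79
```

prints (abridged) `"overall": 0.1754`, `"event_component": 0.3146`,
`"z": 2.050`, `"p_value": 0.0404`: a net 31% of events and −14% of
non-events are reclassified correctly, an overall NRI of 0.175 that is
significant at the 5% level.

The same analysis end-to-end on a synthetic cohort:

```python
from strokemarker import (SimulationParams, generate_cohort, fit_logistic,
                          delong_test, category_free_nri)
from strokemarker.risk import MODEL1_COVARIATES, MODEL2_COVARIATES

cohort = generate_cohort(SimulationParams(n=168, seed=20130722))
m1 = fit_logistic(cohort, MODEL1_COVARIATES)
m2 = fit_logistic(cohort, MODEL2_COVARIATES)
print(m2.summary().round(3))
cmp_ = delong_test(m1.fitted, m2.fitted, cohort.unfavourable())
print(f"AUC model 1 = {cmp_.auc1:.3f}, model 2 = {cmp_.auc2:.3f}, "
      f"DeLong p = {cmp_.p_value:.3f}")
nri = category_free_nri(m1.fitted, m2.fitted, cohort.unfavourable())
print(f"category-free NRI = {nri.overall:.3f} (p = {nri.p_value:.3f})")
```

```
                 coef     se     OR  or_low  or_high      z      p
const          -7.842  1.537  0.000   0.000    0.008 -5.102  0.000
age             0.087  0.020  1.090   1.049    1.133  4.408  0.000
nihss           0.223  0.057  1.249   1.116    1.398  3.872  0.000
recanalization -0.238  0.366  0.789   0.385    1.615 -0.649  0.516
mr_proadm      -0.128  0.522  0.880   0.316    2.447 -0.246  0.806
AUC model 1 = 0.798, model 2 = 0.799, DeLong p = 0.535
category-free NRI = 0.024 (p = 0.879)
```

Age and NIHSS carry strong signal (OR 1.090 per year, 1.249 per NIHSS
point); at n = 168 the biomarker's estimated OR is dominated by sampling
noise (its generating OR, 4.062 per nmol/l, corresponds to roughly 0.5
standard deviations of risk on the logit scale), which is exactly why the
reclassification machinery — more sensitive than the AUC comparison — exists.
At n = 100,000 the fit recovers all four generating odds ratios to within a
few percent (see the tests).

The command-line interface mirrors the library: `strokemarker simulate`
writes a synthetic cohort CSV, `strokemarker run --cohort c.csv --out
report.json` produces a structured JSON report (models, AUC comparison, both
NRIs, KM curves and log-rank tests, provenance) that validates against the
schema shipped in `strokemarker/schema/`.

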