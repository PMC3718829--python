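# Methods

## Problem and estimands

The package quantifies the *incremental* prognostic value of a continuous
plasma biomarker (MR-proADM, nmol/l) for the dichotomized 90-day functional
outcome after acute ischemic stroke. The outcome is unfavourable when the
modified Rankin Scale at day 90 is 3–6 (death, mRS 6, included) and
favourable for mRS 0–2. Four estimands are produced for a cohort:

1. odds ratios of a baseline logistic model (age, NIHSS, recanalization) and
   of the biomarker-augmented model;
2. the difference of the two models' AUCs with DeLong's paired test;
3. the category-free NRI between the two models' predicted risks, and the
   categorical NRI of the SPAN-100 → SPAN-100 + biomarker-quintile rule;
4. Kaplan–Meier curves and log-rank tests of 90-day death across biomarker
   quintiles.

## Models and statistics

**Logistic fits.** Maximum likelihood via IRLS (statsmodels GLM, binomial
family, logit link), convergence on relative log-likelihood change below
1e−10 with at most 50 iterations; standard errors from the inverse
information (observed = expected under the canonical link). Wald 95% CIs use
z = 1.96 exactly. Quasi-complete separation is reported as an error when a
coefficient exceeds 15 on the logit scale while fitted risks pin to 0/1 (or
the fit fails to converge); a singular design raises a collinearity error
naming the dependent columns found from the smallest right-singular vector.
Backwards elimination drops the non-forced covariate with the largest Wald
p-value above the removal threshold (default 0.10) and refits. The default
pipeline *forces* all covariates of both models: the clinically established
baseline (including a non-significant recanalization term) is kept by design
rather than re-selected per cohort.

**SPAN-100.** Score = age in years + admission NIHSS; positive when strictly
greater than 100. A score of exactly 100 is classified negative: the defining
rule names only ">100 positive" and "<100 negative", and the boundary is
resolved to non-positive here.

**Quintiles.** Two binning modes are provided because the two natural
readings of "biomarker quintiles" differ: `empirical-quantile` (default)
cuts at the 20/40/60/80th percentiles with linear interpolation between
order statistics, intervals closed on the right at each cut;
`equal-width` splits [min, max] into five equal intervals (last closed),
which is the reading implied by published per-quintile concentration ranges
of equal width. Neither is asserted to be "the" study rule; the choice is a
config option.

**AUC and DeLong.** Placement values with midranks throughout (fitted risks
can tie on discrete covariates). For events x (m of them) and non-events y
(n), V10_i = (#{y < x_i} + ½#{y = x_i})/n and symmetrically V01_j; AUC =
mean(V10) = mean(V01). For two score vectors on the same subjects,
Var(AUC₂−AUC₁) = cᵀ(S10/m + S01/n)c with c = (−1, 1) and S10, S01 the 2×2
empirical covariance matrices of the paired placement values;
z = ΔAUC/√Var with a two-sided normal p. A variance below 1e−15 (e.g.
rank-identical scores, as under any monotone transform) raises a degenerate-
comparison error instead of dividing 0 by 0.

**NRI.** Both variants share components NRI_e = (up_e − down_e)/n_e,
NRI_ne = (down_ne − up_ne)/n_ne, overall = NRI_e + NRI_ne, and the simple
asymptotic z = overall / √((up_e+down_e)/n_e² + (up_ne+down_ne)/n_ne²),
with per-component z analogously. This variance form reproduces the
published p = 0.04 on the published table counts, and its per-component
p-values fall below the published <0.001 (events) and <0.01 (non-events)
bounds. For the category-free variant a risk change within ±1e−12 counts as
a tie: risks from two nested fitted models are generically distinct, so
exact ties are numerical artifacts, not information.

**Survival.** Product-limit estimator with the standard tie convention
(censored-at-death-time observations remain at risk at that time) and
Greenwood variance. The k-group log-rank statistic accumulates, at each
distinct death time, observed minus expected deaths per group and the
multivariate hypergeometric covariance, then forms the chi-square on the
first k−1 components (pseudo-inverse for safety). The trend variant is
(cᵀ(O−E))²/(cᵀVc) with scores c = 1..k on 1 df. Both the overall and trend
p-values are reported: with ordered groups and a monotone hazard
alternative either may be the analyst's choice, and the source analysis does
not say which it used.

## Synthetic-cohort generator

The generator emulates the joint structure the analysis relies on, with
defaults set to the study cohort's published summaries (chosen once, as the
study conditions, not as tuning knobs):

| parameter | default | rationale |
|---|---|---|
| n | 168 | study cohort size |
| age | truncated normal, mean 72.9, sd 13.5, range 18–97 | published mean/range; sd chosen to be realistic for a stroke unit |
| NIHSS | discretized truncated log-normal on 4–25, median 9, log-sd 0.42 | published median/range; right-skew typical of admission NIHSS |
| biomarker | log-normal, median 0.74 nmol/l, log-sd 0.45 | between-group medians 0.84/0.68 bracket the overall median; log-sd gives a realistic 0.2–2.2 nmol/l span |
| Spearman (biomarker, age) | 0.34 | published |
| Spearman (biomarker, NIHSS) | 0.18 | published |
| recanalization | Bernoulli(0.536), independent | published rate; no NIHSS difference was reported between treated/untreated |
| outcome log-ORs | ln 1.090 (age), ln 1.187 (NIHSS), ln 0.732 (recanalization), ln 4.062 (biomarker) | the full multivariable model's odds ratios as generating effects |
| intercept | −8.6494 | calibrated so the expected unfavourable rate is 89/168 (root-finding on the smooth Monte-Carlo event rate, 2×10⁶ draws) |
| death among unfavourable | base 0.28 × quintile multipliers (0.45, 0.70, 1.0, 1.35, 1.75) | reproduces ≈30/89 deaths with risk rising in biomarker quintile |

Rank correlations are induced by a Gaussian copula using the exact latent
conversion r = 2·sin(π·ρ_S/6); the NIHSS discretization attenuates its
realized Spearman correlation by well under 0.01. Death (mRS 6) is drawn only
among unfavourable outcomes; its day is uniform on 1–90 and survivors are
censored at day 90. Non-fatal mRS values are uniform within {0,1,2} or
{3,4,5} — only the dichotomy and death matter downstream. All randomness
flows from a single seeded `numpy` generator (default seed 20130722); fixed
seed means bit-identical cohorts.

**What the generator does not emulate:** comorbidity structure (atrial
fibrillation, hypertension and stroke subtype are not simulated, though the
cohort format carries them), medication effects on the biomarker,
measurement timing (0–24 h from onset), non-uniform death timing within the
90 days, and the possibility that the real biomarker–outcome relation is
non-logistic in shape. Passing tests therefore demonstrate that the
*machinery* is correct and calibrated under the assumed structure, not that
the biomarker's clinical effect replicates in new patients.

## Numerical and design choices

* Quantile definition: linear interpolation between order statistics (the
  common statistical-package default).
* Event-rate calibration does root-finding on the *expected* rate
  mean(expit(b0 + lp)) over a large fixed covariate draw — smooth and
  strictly increasing in the intercept, so Brent's method is reliable; the
  residual tolerance is 0.005.
* Missing data: complete-case; a row missing any required field is rejected
  with a log entry. A survivor's blank follow-up is forced to 90 days
  (administrative censoring); a death must state its day — how deaths were
  dated in the source cohort is unknown, so day-level dating is an input
  contract here, not an inference.
* Report determinism: the JSON report is a pure function of cohort and
  config (no timestamps); the provenance block carries the config hash,
  seed and package version.
* Problem sizes in the test-suite: calibration targets are checked at
  n = 100,000; coefficient recovery averages eight replicate cohorts of
  n = 100,000 (the recanalization log-OR is small, |ln 0.732| ≈ 0.31, and
  its single-cohort sampling SE at that n is comparable to a 5% relative
  band, so averaging tests consistency rather than a coin flip); type-I
  error of DeLong and the 5-group log-rank uses 1,000 null replicates;
  the DeLong variance is cross-checked against a 2,000-replicate paired
  bootstrap at n = 500.

## Known limitations

* The original patient-level results (AUC 0.803/0.819, category-free NRI
  0.577, log-rank p = 0.011, between-group medians) are functions of an
  undeposited cohort and cannot be reproduced; the package reproduces the
  one patient-level quantity whose inputs are published (the categorical NRI
  from the reclassification-table counts) and validates everything else
  against oracles and calibrated simulations.
* No Firth/penalized regression: cohorts with separation raise an error
  rather than being rescued.
* No integrated discrimination improvement (IDI), AUC confidence bands or
  Cox regression — outside the pipeline's scope.
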