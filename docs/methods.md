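# Methods

## Scope and model

`pdcogrisk` implements three baseline risk scores for 5-year cognitive
decline in de novo Parkinson's disease (PD), the composite cognitive
outcome they are evaluated against, and the evaluation harness itself.

**Outcome.** Five neuropsychological tests — JLO (visuospatial), SDMT
(processing speed / executive), semantic fluency (language), HVLT-DR
(memory) and LNS (working memory) — are each converted to a z-score. HVLT-DR
arrives as a T-score (z = (T − 50)/10) and LNS as a scaled score
(z = (s − 10)/3); the three raw-score tests use a user-supplied normative
mean/SD stratified, optionally, by age band, education range and sex. The
composite cognitive score (CCS) is the arithmetic mean of the available
z-scores, and a participant *declines* when CCS drops by ≥ 0.5 z-units from
baseline to year 5 (a drop of exactly 0.5 counts as decline; the threshold
is a parameter). The default composite policy is `require_all` — both
visits need the full five-test battery, mirroring a complete-case analysis
cohort — with `mean_available` offered for exploratory use. The 0.5
threshold is interpreted in composite z-units (the CCS is already an
SD-scaled quantity), not as 0.5 of the cohort's empirical CCS SD; the
parameter makes the alternative reading available.

**Scores.** All factor definitions live in a YAML registry
(`data/registry.yaml`): per factor, its input field(s), comparison operator
(`ge/gt/le/lt/eq/flag/any_of/count_ge`, plus banded lookups), cutoff and
point weight. The packaged defaults are:

- **LIBRA** (weighted, 9 factors as computable from PPMI-like data):
  age-by-sex bands (0 below 65 up to 16.4/17.6 at ≥90 for men/women),
  education bands (≥13 y: 0; 8–12 y: 1.4; ≤7 y: 2.7), depression
  (GDS-15 ≥ 5, 2.1), obesity (BMI ≥ 30, 1.6), physical inactivity
  (PASE ≤ 90, 1.1), hypertension 1.6, hypercholesterolemia 1.4, diabetes
  1.3, coronary heart disease 1.0. High risk at ≥ 4.2. Smoking, alcohol,
  diet and cognitive-activity components are intentionally absent (not
  reliably collectable in the emulated cohort) but can be added via a
  custom registry. Maximum attainable total of this registry: 30.4.
- **MoPaRDS** (8 one-point factors): age ≥ 70, male sex, MoCA < 26,
  orthostatic SBP drop > 10 mmHg, bilateral onset, falls/freezing
  (UPDRS 2.12 > 1 and/or 2.13 > 0), RBDSQ > 5, hallucinations
  (UPDRS 1.2 > 0). High risk at ≥ 4.
- **pPREDICT** (14 one-point factors): age ≥ 65, male sex, non-white
  and/or Hispanic, education ≤ 12 y, MoCA < 26, disease duration ≥ 5 y,
  RBDSQ ≥ 5, UPDRS III ≥ 32, GDS-15 ≥ 8, STAI-S ≥ 54, ESS ≥ 11,
  BMI ≥ 25, PASE ≤ 90, and ≥ 2 of {CAD, stroke/TIA, hypercholesterolemia,
  hypertension, diabetes}. High risk at ≥ 4. Weights are fixed at one
  point; no weighting option is offered.

Two deliberate readings where the source material is internally
inconsistent: (1) LIBRA's physical-activity direction awards its 1.1 points
for *inactivity* (PASE ≤ 90), consistent with the pPREDICT definition and
with the stated choice of PASE > 90 as the moderate-intense activity
cutoff; (2) the "medium" education band is the gap between the printed low
(≤ 7) and high (≥ 13) bands, implemented as the half-open interval
[8, 13) on education in years.

**Missing data.** Scoring takes a `missing_policy`: `error`, `omit_factor`
(default — the factor is skipped and recorded, following the established
practice of omitting LIBRA components a cohort cannot supply), or
`impute_absent` (missing = factor absent). `validate_for_scale` reports
which factors of a scale a record cannot answer. The `any_of`
falls/freezing factor scores from whichever of its two items is present,
matching its "and/or" definition.

**Evaluation.** Predicted-positive is score ≥ cutoff (defaults 4.2/4/4).
Sensitivity, specificity, accuracy, LR+ = sens/(1 − spec) and
LR− = (1 − sens)/spec follow the usual identities, with the boundary cases
encoded as ±inf/NaN rather than raised. The AUC is the Mann–Whitney
statistic with ties counted 1/2; its variance and the covariance between
correlated curves use the DeLong structural-components estimator (midrank
implementation, O(N log N)), giving 95% CIs (a seeded stratified bootstrap
is available as a cross-check) and a k-curve equality test: the quadratic
form of the AUC differences against their DeLong covariance, chi-square
with k − 1 df (pseudo-inverse for the degenerate identical-curves case,
which returns statistic 0, p = 1). Regression models of CCS change are
ordinary least squares with intercept via statsmodels, either on the total
score or on the per-factor contribution matrix; constant and collinear
columns are dropped with a warning, rows with omitted factors are excluded
from the per-factor model, and no multiple-testing correction is applied to
per-factor p-values (mirroring how such models are conventionally
reported). The regression outcome is the signed CCS change
(follow-up − baseline; negative = worsening).

## Synthetic cohort generator

The generator emulates the structure of a de novo PD cohort so the full
pipeline is testable without controlled-access data.

- **Marginals.** Continuous variables are truncated normals whose
  *truncated* mean/SD equal the configured targets (age 60.8 ± 9.8 on
  [30, 95], ESS 5.7 ± 3.2 on [0, 24], MoCA 27 ± 2.3 on [0, 30],
  UPDRS III 20 ± 8.5, RBDSQ 3.1 ± 2.5, PASE 178.7 ± 105.4, GDS-15
  5.2 ± 1.5, STAI-S 47.2 ± 5.4, BMI 27.1 ± 4.5, education 15.7 ± 2.9);
  the underlying location/scale are solved by root-finding, since naive
  truncation at hard floors would shift means (ESS by ≈ +0.27). Questionnaire
  totals are rounded to integers. Symptom duration is log-normal with
  matched mean/SD (61.7 ± 56.7 months) reflecting its right skew; disease
  duration in years is its /12. Binary prevalences: male 66.1%, non-white
  and/or Hispanic 8.5%; fields the cohort table does not report are chosen
  once at plausible values for early PD (hallucinations 5%, freezing 7%,
  UPDRS 2.12 ∈ {0,1,2} at 70/26/4%, bilateral onset 15%, hypertension 35%,
  hypercholesterolemia 35%, diabetes 8%, CAD 6%, stroke/TIA 3%, orthostatic
  SBP drop ~N(2, 8) mmHg truncated to [−30, 60] so ≈ 16% exceed the
  10 mmHg cutoff). Variables are independent by default (no covariance
  information exists for the emulated cohort); a Gaussian copula accepts
  explicit pairwise correlations.
- **Planted decline.** Decline status is Bernoulli from a logistic
  propensity over *standardized latent* variables — not over any score or
  dichotomized indicator — so no scorer is trivially encoded. Default
  log-odds per SD: age 0.7, ESS 0.7, UPDRS III 0.5, RBDSQ 0.5, MoCA −0.35,
  education −0.2, GDS 0.2, STAI-S 0.2, BMI 0.25, PASE −0.3; per level:
  male 0.5, hallucinations 0.9. Discrimination therefore arises from many
  weak associations, as in real cohorts. The intercept is solved per cohort
  so the mean propensity equals `base_decline_rate` (default 44/307 ≈
  14.3%) exactly, which makes the null configuration (all effects zero)
  behave as a pure Bernoulli draw.
- **Cognition.** A latent ability g ~ N(0.13, 0.556) plus per-test scatter
  (SD 0.5) yields baseline test z-scores whose composite has SD ≈ 0.6.
  Decliners' year-5 z-scores are shifted down by `decline_shift`
  (default 0.8) plus test-retest noise scaled so the CCS-level change noise
  has SD `noise_sd` (default 0.15); maintainers get noise only. Raw scores
  are produced by inverting the packaged *synthetic* normative reference
  (JLO 24 ± 4, SDMT 45 ± 10, fluency 21 ± 5 — plausible values, not manual
  norms) and rounding, so the raw → z → CCS path is exercised, including
  mild ceiling effects (JLO is clipped at 30, affecting ≈ 3–5% of draws).
- **Calibration.** `decline_shift` and the effect log-odds were fixed once
  so that, at the emulated cohort size (n = 307, 50 replicates), the
  observed decliner fraction sits at ≈ 14% and the mean pPREDICT AUC falls
  near the middle of the published interval [0.60, 0.76] (measured ≈ 0.68,
  with LIBRA ≈ 0.61 and MoPaRDS ≈ 0.63 preserving the published ordering).
  This is a plausibility envelope, not a reproduction: the generator does
  not model PPMI's joint distribution, attrition or missingness.

**What passing tests do not show.** Synthetic success demonstrates internal
consistency (definitions, arithmetic, estimator behaviour), not clinical
validity: real cohorts have correlated risk factors, informative dropout,
practice effects on repeat testing, and normative tables with demographic
strata, none of which the defaults emulate.

## Numerical choices

- Threshold comparisons are exact (`>=`, `>`, `<=`, `<`, as printed per
  factor); band intervals are half-open [min, max).
- A CCS drop of exactly the threshold is decline; trajectory is computed
  from `baseline − followup` while the stored `ccs_change` is
  `followup − baseline`.
- DeLong CIs are clipped to [0, 1]; constant score vectors are flagged
  degenerate with AUC 0.5 and a zero-width CI.
- The moment-matching root-solve for truncated normals is cached per
  (mean, sd, lo, hi) and rejects infeasible targets.
- OLS drops constant columns, then greedily drops columns that break the
  design's full rank, reporting both; it refuses n ≤ p + 1.
- All randomness flows from a single `numpy.random.default_rng(seed)` per
  generated cohort; identical config + seed reproduces the cohort
  bit-for-bit.

## Problem sizes used in the checks

Marginal checks run at n = 10,000 (3-standard-error tolerances); oracle
equivalence at 1,000 random records and 100 small ROC instances (n ≤ 30,
exhaustive pair counting); OLS parameter recovery at n = 5,000 with planted
coefficients −0.25 (age ≥ 65) and −0.47 (ESS ≥ 11) and noise SD 0.3;
DeLong coverage over 500 binormal cohorts of 150 + 150 at true AUC
Φ(1/√2) ≈ 0.760; the simulation envelope over 50 replicates of n = 307.

## Known limitations

- The LIBRA registry covers the nine factors computable from the emulated
  data; cohorts with smoking/alcohol/diet/cognitive-activity measures must
  extend the registry themselves.
- Only two visits (baseline, year 5) are modelled; no time-to-event or
  trajectory-imputation support.
- The DeLong k-curve test is asymptotic; at very small n its p-values can
  drift from the permutation answer by a few hundredths (the test suite
  bounds this at 0.15 on n = 40 fixtures).
- `mean_available` composites at different visits may average different
  test subsets; the package records `n_tests_used` but does not adjust for
  differential reliability.
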