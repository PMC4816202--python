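# Methods

This note records the modelling conventions, default parameter choices and
numerical decisions behind `scadcost`, and what the synthetic-data tests do
and do not establish about real linked-EHR data.

## Time grid and cohort conventions

All models share a 90-day cycle grid; an analysis "year" is four cycles
(360 days), and cycle→year conversion for discounting and life expectancy
uses 365.25 days per year. Cohort entry is at the diagnosis date for stable
angina and unspecified CHD, and a fixed 182 days (six months) after an acute
coronary syndrome — a fixed offset keeps entry dates reproducible across
calendar conventions. Two analysis windows are derived per patient: the
first cohort year (cycles 1–4) and, after a non-fatal first event, the four
cycles starting at the event cycle. Windows cut short by non-death censoring
(transfer out, administrative end) are excluded from cost summaries; windows
ending in death are retained and cost accrual stops at death.

Events are timed at cycle end: a patient whose AMI falls in cycle k accrues
the band-1 event cost in cycle k, and a patient dying in cycle k accrues
that cycle's state cost plus the death-period increment.

## Cost categories

Each 90-day cost row is split into components with a fixed nesting:
CHD inpatient ⊆ CVD inpatient ⊆ all inpatient, and CVD drugs ⊆ all drugs.
Reported categories compose as

* total = inpatient + primary care + diagnostics + all drugs,
* CVD = CVD inpatient + primary care + diagnostics + CVD drugs,
* CHD = CHD inpatient + primary care + diagnostics + CVD drugs,

so CHD ≤ CVD ≤ total holds row-wise by construction. Share statistics are
ratios of means (×100), not means of ratios — this is the convention that
reproduces published table shares from published means exactly. Summary SDs
use the n−1 denominator.

## Synthetic-data generator

The generator emulates the study conditions of a large English SCAD cohort:

* **Demographics** — 44% female; ages normal with means 67 (men) and
  72 (women), SD 9 years, truncated to [35, 95]; diagnosis mix 47.4% stable
  angina / 13.5% unstable angina / 6.7% STEMI / 9.7% NSTEMI / 22.6% other
  CHD. Comorbidity prevalences (heart failure 8%, renal disease 5%,
  diabetes 16%, COPD 11%, cancer 8%, current smoking 19%) and the biomarker
  set (heart rate, creatinine, haemoglobin; ~18–25% missing, MCAR by
  default with an optional age-dependent mechanism) are not printed in the
  available source and are set to values typical for a UK SCAD population.
* **Events** — discrete-cycle competing risks: per cycle, cause-specific
  exponential rates are converted to probabilities
  p_c = h_c/H·(1 − e^{−H}); after a non-fatal first event only the two death
  transitions remain (recurrent non-fatal events are out of model scope).
  Baseline rates at the male/age-69/no-comorbidity reference are
  AMI 0.0035, ischaemic stroke 0.0018, haemorrhagic stroke 0.0004, CVD death
  0.0018 and non-CVD death 0.016 per cycle, with log hazard ratios of
  0.085/year of age on the CVD transitions and 0.05/year on non-CVD death.
  The CVD slope spans a 5-year event risk of roughly 3.5%–40% between ages
  52 and 84, matching the published decile range; the flatter, higher
  non-CVD mortality is calibrated so that — with covariates held
  time-invariant during extrapolation (see below) — modelled life
  expectancies bracket the published ~27-year (youngest decile) to
  ~5.5-year (oldest decile) span. Censoring is an independent per-cycle
  Bernoulli (1%/cycle), reflecting the assumption that non-death censoring
  is ignorable.
* **Costs** — the ground-truth total-cost structure is the published worked
  example: £341 baseline per 90 days, +£10 per subsequent period, AMI
  event-cycle increment £5028 with £521/cycle long-run, death-period
  increments £2008 (CVD) and £2240 (non-CVD). Bands 2–4 are not printed in
  the available source; they are chosen to decay so first-year incremental
  event costs equal the published totals (£7677 AMI, £8902 ischaemic
  stroke, £10 477 haemorrhagic stroke). Each increment and the background
  cost are split across components by fixed shares (AMI costs are mostly
  CHD hospitalization, stroke costs mostly non-CHD CVD hospitalization,
  non-CVD death mostly non-CVD hospitalization), which simultaneously
  defines the implied CVD/CHD category parameters in closed form and
  guarantees the category nesting row by row. Component costs are
  independent gamma draws with shape k = 0.5 (right-skewed, CV ≈ √2 per
  component) and scale mean/k. Utilization counters are stylised:
  hospitalization probability rises with the period's expected inpatient
  cost (p = 1 − e^{−mean/£600}), stays/length-of-stay are shifted Poisson,
  drug-class flags are persistent per patient.

What the generator does **not** emulate: coding-system artefacts, seasonal
or calendar-time effects, cost inflation, correlated component noise,
informative censoring, recurrent non-fatal events, and covariate drift
(ageing) during follow-up. Passing tests therefore demonstrate that the
estimators recover the truth under the model's own assumptions — not that
those assumptions hold in any particular EHR extract.

## First-year cost regression

Gamma GLM with log link (statsmodels IRLS) of first-year total cost on
sex, age, diagnosis (stable angina reference), comorbidities and centred
biomarkers. Missing biomarkers are completed by chained equations —
predictive mean matching (Bayesian-perturbed OLS prediction, five nearest
donors) for continuous columns, logistic draws for binary columns, five
sweeps — M = 5 completed data sets, pooled with Rubin's rules
(T = W + (1+1/M)·B, normal-approximation CIs on the log scale). The
imputation is implemented in-package so that all draws flow from a single
seeded generator: given a seed the full pipeline is bit-reproducible, the
no-missing-data case degenerates to M identical copies, and a fully missing
column is rejected by name.

Zero-cost patients: the gamma support excludes 0, so annual totals are
floored at £0.01 by default (configurable; `floor=None` demands strictly
positive costs). Natural-scale £ increments use recycled predictions — the
cohort-average difference in predicted cost with a binary covariate
switched on vs off, or a continuous covariate shifted by its reporting unit
(10 years for age, one observed SD for biomarkers) — with CI bounds by
endpoint transformation of the coefficient CI (respects positivity; the
difference from the delta method is second order).

## Panel cost model

Pooled least squares of per-cycle cost on intercept, elapsed-cycle trend,
time-invariant covariates, event×band indicators (bands 1–4 then a
long-run indicator per event type) and death-cycle indicators, with
patient-clustered covariance. The additive-on-£ estimator is a deliberate
modelling choice: the published cost structure (a £ baseline plus £
per-period trend plus £ increments) is additive on the natural scale. Only
the first non-fatal event carries increments. Indicator columns with no
support (e.g. no haemorrhagic strokes in a small cohort) are dropped with a
warning and reported as 0; genuinely collinear designs raise an error
naming the aliased columns. Predictions are floored at £0 with a warning.

## Multistate model

Per state (Stable with five competing causes; post-event with two), the
discrete-cycle likelihood collapses to per-patient sufficient statistics
(cycles at risk, observed cause), making the fit O(n) per evaluation. The
mean log-likelihood is maximised by L-BFGS-B with an analytic gradient;
standard errors come from the observed information obtained by central
finite differences of the gradient. Baseline log-hazards are bounded below
at log(1e-8): a cause with an empty risk set is pinned at the floor with
its covariate effects fixed at zero and a warning. Post-event mortality is
pooled across the three non-fatal event types by default
(`share_post_event_hazards=True`), matching the generator and avoiding
unstable stroke-specific death hazards in modest cohorts; per-event
estimation is available. Covariate effects are proportional on
cause-specific hazards and time-invariant.

## Lifetime engine

The 18-state realisation (Stable; four one-cycle tunnel states plus a
long-run state per non-fatal event type; two absorbing death states) lets a
time-homogeneous Markov chain carry the panel model's time-since-event cost
bands exactly. The cohort trace uses the post-transition convention:
occupancy after cycle k's transitions prices cycle k, so new events carry
their band-1 cost in the event cycle, and the mass flowing into death
accrues its origin-state cost plus the death increment. Survival is the
alive-state occupancy; life expectancy is Σ survival(k) × 90/365.25
(end-of-cycle convention: a cohort absorbed in cycle 1 has life expectancy
0). The 5-year event risk has the closed form
p_cvd·(1 − s^20)/(1 − s) with s = e^{−H}, since stable-state transition
probabilities are constant.

Discounting: 3.5% per annum, mid-cycle convention
(1+r)^{−(k−0.5)·90/365.25} by default — standard health-economics practice
when costs accrue throughout a period — with end-of-cycle available. No
half-cycle correction is applied to cost accrual itself: the 90-day panel
already discretises accrual. The default projection horizon is 400 cycles
(~98.6 years); if residual survival at the horizon exceeds 1e-4 a warning
reports the truncation. Because covariates (including age) are held
time-invariant during extrapolation, young low-risk profiles keep their
entry-age hazards indefinitely; their lifetime projections are optimistic
and horizon-sensitive, which is the main known limitation of the
extrapolation and the reason the non-CVD mortality defaults are calibrated
at the cohort level rather than taken from period life tables.

The microsimulation oracle samples individual paths from the identical
transition matrix and prices them with the identical deterministic state
costs, so trace-vs-microsimulation agreement (within Monte Carlo error)
checks the propagation and accounting, independent of the estimators.

## Risk-decile reporting

Patients are ranked by modelled 5-year CVD event risk and split into ten
rank groups (sizes differ by ≤1; ties broken by patient id). Each decile's
representative profile uses covariate means, with binary covariates entered
as prevalences (fractional values) — this preserves decile-average risk
better than modal values; a modal option exists. Report rounding follows
the published precision: £ to the nearest integer, shares to 1 decimal,
risks to 2 decimals. Exports are atomic (temp file + rename) and
byte-reproducible given seed and config.

## Problem sizes

Default test and acceptance problem sizes were chosen as the smallest that
leave Monte Carlo error well below the effects under test: n = 100 000 for
baseline covariate fractions, n = 50 000 for event closed forms, n = 10 000
patients for panel-parameter recovery (n = 40 000 in the acceptance script's
recovery block), n = 20 000 for multistate recovery and decile signatures,
200 000 paths for trace-vs-microsimulation checks, and 50 replicates at
n = 5000 for gamma-GLM CI coverage.
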