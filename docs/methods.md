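# Methods

This note documents the generative model behind the synthetic cohort, the
processing and estimation procedures, the numerical choices, and what the
passing tests do and do not establish about real data.

## Study design being emulated

A one-year, two-arm quasi-experimental workplace study: an intervention arm
of 172 office workers whose departments scheduled short active breaks
(~10 min/day) into the 09:00–17:00 workday, and a control arm of 323 office
workers from the same company group who worked as usual.  Assignment was
not randomized; the arms differ systematically at baseline (controls are
older, more often male, heavier, more often managers, and more sedentary),
so the analysis must remove measured confounding.  Outcomes are measured at
baseline and at one year: occupational movement behaviors from a waist-worn
triaxial accelerometer, and three self-report scales.

## Synthetic cohort

### Covariates and assignment

Arm sizes are fixed by design (172/323).  Covariates are drawn
arm-conditionally — age and BMI normal, sex and managerial position
Bernoulli — with arm-specific parameters calibrated to the published
baseline table.  Drawing covariates conditional on the arm is equivalent to
a population model with a logistic-family true propensity score (Bayes'
rule applied to exponential-family conditionals), so the fitted logistic
propensity model downstream is approximately correctly specified.  A scalar
`confounding` knob interpolates every arm-conditional parameter toward the
pooled value; at 0 the arms are exchangeable, which the null-calibration
tests exploit.

### Latent behavior profiles

Each subject-visit carries latent standardized targets for SB, LPA and
MVPA minutes per 8-hour day, summing to exactly 480 (standardized minutes
are compositional).  Between-subject deviations use a zero-sum basis:
the MVPA deviation and the LPA residual are centered gamma variables
(shape 3 — bounded below, right-skewed, as activity-time distributions
are), correlated so the implied SB deviation has the published
between-subject SD.  Feasibility requires sd(SB) ≤ sd(LPA) + sd(MVPA),
which the published SDs satisfy in both arms.

Follow-up deviations are a **random walk** from baseline: baseline
deviation plus an independent zero-sum increment whose SDs reproduce the
published change-score confidence-interval widths.  This makes change
scores mean-independent of baseline, so the arm-level programmed change is
the estimand in *any* covariate-weighted subpopulation — the property that
makes "recover the programmed change" a well-posed check for an
overlap-weighted estimator.  (An autoregressive tracking model was
considered and rejected: mean-reverting changes turn the weighted
within-arm change into a different estimand whenever baselines are
confounded.)  The cost is that follow-up marginal SDs are mildly wider
than the printed follow-up SDs; those descriptives are not targets.

The published intervention-arm changes (−24.4 / +12.6 / +10.1 min for
SB / LPA / MVPA) do not sum to zero, but compositional changes must; the
defaults redistribute the 1.7-minute imbalance equally
(−23.833 / +13.167 / +10.667; control +1.467 / −2.033 / +0.567).  These
adjusted values are the programmed estimands.

### Epoch streams

Each wear day is a first-order Markov chain over
{non-wear, SB, LPA, MVPA}, one state per 60-s epoch across the 480-slot
work window, initialized from its stationary distribution.  The transition
matrix has stay probabilities 1 − 1/t_s on the diagonal (t_s the target
mean run length) and off-diagonal mass from a zero-diagonal jump chain Q
whose stationary law is the leave-flow distribution ν_s ∝ π_s/t_s, fitted
by iterative proportional scaling of ν νᵀ to margins ν with a zero
diagonal.  This yields *exact* stationary occupancy π and geometric runs
with mean t_s.  Feasibility requires max(ν) ≤ 1/2 (a state cannot receive
more than half of all state changes); when a very sedentary subject's
profile violates this, the other states' dwells are shortened first
(floor 2 min) — busier sitters take shorter breaks — and only then is the
SB dwell lengthened to the boundary.

Default dwell times (min): non-wear 150, SB 10 (intervention) / 13.7
(control), LPA 6.5/6, MVPA 5.  The SB dwells calibrate prolonged-SB time
(~58 vs ~110 min/8 hrs at baseline) and the PA dwells the bouted-PA band,
against the published baseline table.  The long non-wear dwell keeps most
zero-runs above the 60-min detection threshold; short zero-runs count as
wear and are tallied as SB (MET 0 is below the 1.5-MET cut-point), which
both keeps SB + LPA + MVPA ≡ wear time and mildly dilutes standardized
changes — at 150 min dwell the dilution is ≲ 0.1 min and within
Monte-Carlo tolerance.

MET values per state: 0 for non-wear; uniform 0.9–1.5 (SB); uniform
1.6–2.9 (LPA); 3.0 + Exponential(0.5) (MVPA); all rounded to the device's
0.1-MET resolution.  Steps are Poisson with rate proportional to MET
during activity epochs (9.19 and 10.46 steps per MET-minute by arm,
calibrated to the published daily step counts) and zero otherwise.

Wear protocol: intervention subjects wear the device on N(4.7, 0.5)
workdays, controls on N(12.2, 4.5) (rounded, minimum 1).  The per-subject
non-wear fraction is normal with the published wear-time mean/SD, clipped
to [0, 0.20].

### Questionnaire scores

Latent scores are normal with arm-specific baselines; follow-up adds the
programmed change plus independent normal noise (random walk again).
Observation rounds the latent value onto the scale grid and clamps to the
range (K6 integers 0–24; engagement on the 1/9 grid in 0–6; presenteeism
integers 0–10).  Because clamping is nonlinear (the K6 floor holds ~16% of
latent mass), latent means are set by numerically inverting
μ ↦ E[g(N(μ, σ))] with Brent's method so that *observed* arm means and
changes equal the programmed values exactly.  Scores are then decomposed
into items by an even-split rule; standard scoring reproduces the score
exactly (verified by enumeration over the full score lattice).

### Missingness

All mechanisms are MAR.  Device dropout (both visits) follows a logistic
model in age with slope 0.5 per SD and an intercept solved so the
realized arm rate matches its target (0.010 intervention / 0.025 control);
together with subjects failing the ≥ 4-valid-day rule and controls with
< 4 wear days this reproduces the published accelerometer missing counts
(≈ 28/172 and ≈ 17/323).  Covariate and per-visit questionnaire
missingness use the published per-variable rates (covariates effectively
MCAR, a MAR special case); adherence recalls are missing independently at
5.5% per time point, giving ~145 complete cases of 172.  Attrition
(whole-record follow-up loss) defaults to zero.

### Tabular mode

For fast Monte-Carlo work on the estimation stages, `simulate_cohort`
offers a tabular mode that skips epoch simulation and draws subject-level
standardized metrics directly: latent target plus zero-sum day-sampling
noise with the day-level SDs measured from the epoch pipeline
(24.6 / 24.3 / 10.8 min for SB / LPA / MVPA), scaled by 1/√(wear days).
Tabular mode covers SB/LPA/MVPA and the questionnaires only; bout and step
metrics require full mode.

## Processing rules

* Classification: SB (0, 1.5], LPA (1.5, 3.0), MVPA [3.0, ∞); MET 0 is a
  non-wear candidate.  The printed cut-points leave (1.5, 1.6) unassigned;
  the half-open convention classifies every value.
* Non-wear: maximal runs of ≥ 60 consecutive zero-MET epochs; no tolerance
  epochs; shorter zero-runs are wear (counted as SB, see above).
* Working window [09:00, 17:00), epochs labeled by start time; 480 slots.
* Valid day: wear ≥ 75% of the window (≥ 360 min).
* Prolonged SB: maximal unbroken SB runs ≥ 30 min (time and count).
  Bouted PA: maximal unbroken PA runs — LPA and MVPA may mix — of 3–10
  min.  Non-wear breaks every run.  Runs > 10 min are excluded entirely
  by default; a `truncate` switch credits them 10 min each instead, since
  the band's upper edge could be read either way.
* Standardization: raw × 480 / wear minutes, applied to minutes, bout
  counts and steps alike.  Standardized SB + LPA + MVPA ≡ 480 per valid
  day to 1e−9 (asserted).
* Subject summary: unweighted mean over valid days; subjects with < 4
  valid days keep their row with metrics missing, to be imputed.

## Imputation

Chained equations with type-1 predictive mean matching: for each target
variable, an OLS fit on currently observed cases, a Bayesian parameter
draw (normal coefficients, scaled-inverse-χ² variance), least-squares
predictions for donors versus posterior-draw predictions for missing
cases, and a uniform draw among the k = 5 nearest-predicted donors; the
donor's *observed* value is imputed, so imputations live on the observed
support.  Defaults: m = 20 datasets, 10 sweeps, independent sub-seeds per
dataset.  Binary covariates are matched on their numeric coding (donor
values stay in {0, 1}).  Because the three standardized behaviors are
linearly dependent (sum 480), each accelerometer variable's equation
conditions only on its own other-visit value plus all non-accelerometer
predictors; leaving the same-visit complement in the equation makes the
design singular and measurably attenuates MVPA changes.  With zero
missingness the m datasets are identical and the pooled analysis equals
the complete-case analysis exactly (tested).

## Estimation

One propensity model per outcome: logistic regression (IRLS to
convergence, tolerance 1e−10, 100 iterations) of arm on age, sex, BMI,
managerial position, and that outcome's baseline value.  Fitted
propensities at the numerical boundary raise a separation error rather
than being clipped.  Overlap weights are 1 − e for the intervention arm
and e for controls, untrimmed.  The point estimate is the Hájek contrast
of weighted mean change scores; within-arm weighted mean changes are
reported alongside.

Variance uses the stacked M-estimation sandwich: the logistic score
equations and the two weighted-mean equations are stacked, A is the
empirical negative Jacobian, B the outer-product matrix, and
cov = A⁻¹BA⁻ᵀ/n; the bread's structure makes the intercept-only case
collapse exactly to the classical robust two-sample variance (tested), and
the stacked SE agrees with a 500-resample bootstrap within 10% at n = 200
(tested).  A weights-held-fixed variant is available (`sandwich="fixed"`)
for sensitivity.  Single-dataset inference is normal-based; after Rubin
pooling (T = W + (1 + 1/m)B) inference uses the t distribution with
Barnard–Rubin degrees of freedom (normal when B = 0).

Exact balance — equality of overlap-weighted covariate means across arms,
an algebraic property of the logistic score equations — is asserted at
1e−6 on every analysis run and verified at 1e−8 in tests.

Descriptive pre/post means in the results tables are observed-only (not
pooled over imputations); the pooled quantities are the change and
difference estimates.  Baseline two-group tests are Welch's t for
continuous and Pearson's χ² for categorical variables.  Significance is
two-sided at 0.05 with no multiplicity correction, matching the study's
convention.

## Problem sizes

The Monte-Carlo harness runs the full pipeline at 5 wear days per subject
in both arms with outcomes {SB, LPA, MVPA, K6, engagement} and m = 20;
100 replicates take ~3–4 minutes on one core.  The type-I-error and
CI-coverage suites use tabular mode (500 replicates, ~1–2 minutes).  The
default-volume cohort (4.7/12.2 wear days, ~4.4 M epochs) simulates and
processes in ~5 s.

## Known limitations

* The generator emits work-window epochs only; the control arm's full-day
  wear outside 09:00–17:00 is not simulated (it would be discarded by the
  window extraction anyway).
* No day-of-week, seasonal, or within-day (e.g. lunchtime) structure;
  days are exchangeable given the subject profile.
* Follow-up marginal SDs exceed the printed follow-up SDs (random-walk
  consequence, see above); wear time among valid days runs ~25 min above
  the printed mean because invalid (high-non-wear) days are excluded from
  the average.
* Weighted *control-arm* changes for MVPA and K6 carry ~0.1–0.2-unit
  biases relative to the programmed values: the propensity score
  conditions on a noisily measured (or coarsely discretized) baseline
  outcome that also enters the change score, a regression-to-the-mean
  effect intrinsic to weighting on observed baselines.  The published
  design shares this property; recovery checks target the intervention
  arm, where the effect is within Monte-Carlo tolerance.
* Passing recovery tests show the pipeline is faithful to its own
  generative assumptions (MAR missingness, homogeneous effects, no
  unmeasured confounding); they cannot validate those assumptions for the
  real study.
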