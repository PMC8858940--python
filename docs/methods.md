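# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test battery demonstrates.

## The estimation problem

The target quantity is energy expenditure (EE) in kcal per 10-s window,
as measured by indirect calorimetry, during a classic Tabata session:
8 stages of 20 s maximal-effort exercise followed by 10 s of standing rest.
Predictors are wearable-sensor channels: tri-axial activity counts sampled
at 30 Hz at four wear sites (dominant hand, non-dominant hand, right hip,
right ankle) and a per-second heart-rate (HR) trace, plus anthropometrics.
Exercise and interval windows are modelled separately throughout, because
the accelerometer signal is informative only during the bouts (standing
intervals have near-zero counts) while interval metabolism remains elevated
and is driven mostly by HR and body mass.

## Feature construction

Counts are collapsed per sample to the vector magnitude
VM = √(x² + y² + z²) and segmented into contiguous, half-open,
protocol-aligned windows (default 10 s, so a classic session yields 24
windows in the pattern E,E,I per stage).  Per window and site the package
computes the summed VM plus ten distributional statistics of the per-sample
VM values — mean, SD, covariance with the preceding window's VM vector,
min, max, and the 10/25/50/75/90th percentiles — together with the
window-mean HR and the subject's height, weight and sex code
(female = 0, male = 1): 14 model inputs per row.

Conventions, all chosen for unambiguity and testability:

- Percentiles use linear interpolation between order statistics.
- The adjacent covariance of the first window is defined as 0 (it has no
  predecessor), keeping one row per window.
- Window HR is the mean of its seconds; NaN gaps shorter than a window are
  linearly interpolated, longer gaps are an error.
- The per-window VM predictor is the *sum* of per-sample VMs (not the
  mean); stage-level aggregates for the interval model sum over the
  stage's three windows.
- %HRmax uses the conventional 220 − age estimate; METs convert via
  1 MET = 1 kcal·kg⁻¹·h⁻¹.

## Linear models

Candidate sets are fixed presets: for exercise windows, the per-window VM
of each of the four sites, the exercise-window HR and the anthropometrics
(height, weight, sex, age, BMI, body-fat %); for interval windows, nine
stage-level VM/HR aggregates of the reference (right-ankle) site — VM over
0–10 s, 10–20 s, 0–20 s of exercise and the entire stage; HR over the same
spans and during the interval — plus the same anthropometrics.

Pearson correlation (t-test p-values, n − 2 df) ranks candidates by |r| per
period.  Model fitting is stepwise: forward entry of the candidate with the
smallest partial p-value while it is below 0.05, then backward removal of
any included term above 0.10 — the common statistics-package default
consistent with a "retain variables at p < 0.05" rule.  Numerical guards:
candidates that add no variation beyond the current design (duplicates,
exact collinearity) are skipped; once the fit is numerically perfect
(SSR ≤ 10⁻¹² · SStot) forward selection stops, since partial tests on
roundoff residuals are meaningless; 0/0 t-statistics are treated as
insignificant.  OLS fitting, p-values and standard errors come from
statsmodels; the stepwise loop itself is implemented here.

The published exercise and interval equations are provided verbatim as
fixed predictors.  Note a unit oddity carried over deliberately: the
published exercise coefficients imply tens of kcal per 10 s at ordinary
inputs (e.g. 0.193 × 160 bpm ≈ 31 kcal), far above physiological window
EE.  They are evaluated exactly as printed and are not used as generator
defaults.

## The network

A single-hidden-layer perceptron with logsig activations at both layers,
trained by full-batch gradient descent on the MSE with momentum and an
adaptive learning rate:

- after each epoch the candidate step is accepted unless the error grew by
  more than ×1.04; on acceptance the rate grows ×1.05, on rejection the
  step is discarded, the momentum memory is cleared and the rate shrinks
  ×0.7.  The up/down/acceptance constants are fixed here for
  reproducibility; momentum 0.9, initial rate 0.05, ≤ 5000 epochs and an
  error goal of 0.001 are the training defaults.
- the error goal applies to the MSE of *scaled* targets.  Because the
  output unit is a sigmoid, targets are min-max scaled to [0.1, 0.9]
  (headroom against saturation, where gradients vanish) and inputs to
  [0, 1]; constant columns get a unit span so scaling stays invertible.
  Predictions invert the target scaling, so they are bounded by the
  training-target range — a feature for a bounded physiological quantity,
  but it means the net cannot extrapolate beyond EE values seen at fit.
- weights initialise uniformly on [−0.5, 0.5] from an explicit seed.

Hidden width: the candidate list is round(√(n_in + n_out)) + c for
c = 0…11 intersected with [4, 15] (for 14 inputs this is exactly 4…15);
each candidate trains a freshly seeded net and is scored by RMSE on a
seeded held-out quarter of the training rows, ties resolved to the
narrower net.  The pipeline defaults to fixed widths 6 (exercise) and
10 (interval) — the architectures this design settles on — with the sweep
available via `hidden_search`.

The analytic gradients are verified against central finite differences
(norm-relative error < 10⁻⁶) and a hand-derived 1-1-1 single step; this is
the module's master correctness oracle.

## Validation

Splits are by subject, never by window, so no subject contributes to both
fitting and testing: train size is round-half-up of 0.75 n (45 → 34/11),
with an explicit `n_test` override for designs that fix the validation
group size instead (e.g. 15 of 45, which a strict 3:1 ratio cannot
produce).  Metrics:

- MAPE in percent.  Default denominator is the measured value; an
  "as-printed" option divides by the predicted value instead, because both
  conventions appear in the literature.  The MAPE standard error is the SD
  of per-subject MAPEs over √(subjects).
- RMSE in kcal.
- Bland–Altman: differences are measured − predicted, limits are the mean
  difference ± 1.96 × sample SD (n − 1); points exactly on a limit count
  as within.  Under normally distributed differences the within-limits
  percentage converges to 95.0 %, which the acceptance script reproduces
  by seeded simulation at n = 10⁵.
- Per-stage MAPE (8 values per model) and the count of stages above 15 %,
  the conventional upper bound for acceptable EE-prediction error.

## The synthetic generator

Defaults describe a young-adult cohort performing the classic protocol;
every stochastic call takes an explicit seed and is reproducible.

- **Anthropometrics**: truncated normals, age 21.04 ± 2.39 y, height
  1.67 ± 0.075 m, weight 59.61 ± 8.27 kg, body fat 18.46 ± 5.47 %,
  51 % female; BMI is recomputed from the drawn height and weight.
- **HR**: a per-subject exercise plateau (165.46 ± 5.39 bpm men,
  163.88 ± 6.88 women) with first-order kinetics: rise toward the plateau
  during bouts (τ = 15 s) and decay toward plateau − 10 bpm during
  intervals (τ = 40 s), white measurement noise (SD 2 bpm), capped at
  220 − age.  The trace starts at the inter-bout steady level, i.e. it
  emulates the session after the initial on-transient, which keeps the
  exercise-second mean at the configured plateau (the quantity studies
  report).  Consequence: the generator reproduces the *mean* exercise HR
  but compresses the HR range — simulated maxima sit near the plateau
  rather than ~18 bpm above it as real cohorts show (no cardiac drift or
  bout-to-bout escalation is modelled).
- **Counts**: per-axis truncated normals.  Exercise samples use a
  site-specific scale (ankle 75, hands 60/55, hip 50 counts/sample/axis,
  SD = scale/3), multiplied by a per-(site, window) effort factor
  (CV 0.25 — four different movements plus fatigue make between-window
  intensity vary, and making the factors site-independent keeps the four
  site VMs distinguishable for variable selection) and a per-subject
  vigor factor (CV 0.15).  Interval samples sit at a standing level
  (2 ± 1 counts/sample/axis); level 0 produces exactly zero counts.
  At these defaults an exercise window's summed VM is ≈ 40 700 ± 11 500.
- **EE**: per window,
  `EE = 5·10⁻⁶·VM + 0.018·HR + 0.008·BW − 2.2 + curvature + noise`,
  floored at 0, with VM/HR taken from the window itself at the right-ankle
  reference site.  The coefficients were set so that (a) exercise windows
  average ≈ 1.46 kcal/10 s, i.e. ≈ 8.8 METs at the mean body weight, the
  intensity reported for this protocol; (b) HR is the dominant correlate of
  EE, ahead of weight and site VM (the ordering the screening stage should
  find); and (c) interval EE stays elevated (≈ 1.0 kcal/10 s), as indirect
  calorimetry shows during 10-s rests.  The curvature term
  `gain · ((VM/40000) − 1)²` applies to exercise windows only (rests are
  near-resting and modelled linear) and represents the steeper-than-linear
  rise of EE at the highest intensities; the default gain of 1.0 makes the
  linear model's lack-of-fit comparable to the measurement noise
  (SD 0.15 kcal), which is the regime in which a nonlinear learner shows a
  real but modest advantage — the qualitative error structure reported for
  this kind of comparison.  Gain 0 gives an exactly linear cohort on which
  the stepwise fit is exact.

What passing tests therefore show: the mechanics of every stage are
correct, the fitter recovers known generative coefficients, and the network
beats the linear model when and only when the generative relation is
curved.  What they do not show: performance on real sensor data, whose
count distributions, HR dynamics, inter-channel couplings and EE noise are
richer than this generator (no biomechanical movement structure, no
autocorrelated HR error, no device-specific count filtering).

## Problem sizes and runtime choices

The default pipeline simulates 45 subjects (the cohort size the
anthropometric defaults describe) and trains two nets to the full
5000-epoch budget in a few seconds.  The test battery scales its heavier
properties to desk size: coefficient recovery uses 100 cohorts of 30
subjects; the model comparison uses 10 seeded 45-subject pipelines; smoke
tests of the CLI use 4-subject cohorts and shortened training.  Seeds are
fixed everywhere; per-stage seeds derive from one global seed via
`numpy.random.SeedSequence`, so a single integer reproduces an entire run
byte-for-byte.

## Known limitations

- One hidden layer, logsig only, full-batch updates: faithful to the
  modelled design, not a general-purpose network library.
- The interval network uses the interval window's own 14 features; with
  near-constant interval VM statistics its signal comes mostly from HR and
  anthropometrics.
- The stepwise procedure inherits the usual caveats of p-value-driven
  selection (unstable under strong collinearity, optimistic r²); it is
  implemented as specified rather than replaced by regularised
  alternatives.
- `split_subjects` cannot express designs where train and test windows
  come from the same subject; that is deliberate.
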