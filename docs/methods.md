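# Methods

## Feature definitions and conventions

The trend-change features are defined on a window `X` of `N = 6·T` samples
(10-minute sampling).  Runs of equal consecutive values are collapsed to a
single representative before extremum testing, so a flat summit or valley
counts as one trend change; `f1` is the count of *interior* extrema.  The
swing intensities behind `f2`–`f5` are the absolute differences along the
extrema sequence *augmented* with the window's first and last samples.  This
convention is fixed by the worked single-excursion example (60 → 95 → 60
gives `f1 = 1` with four equal intensities of 35): intensities over interior
extrema alone would be undefined for a single extremum.  Other degenerate
choices: a constant window scores `f1 = 0` and all intensities 0 (its only
augmented difference is 0); medians of even-length intensity sequences are
midpoint averages; the descriptive baseline sd uses the n−1 denominator.

Window slicing is half-open: the collection interval covers
`[t0 − (T + horizon), t0 − horizon)` and excludes the sample at the
prediction moment.  Patients whose series do not cover the window on the
exact sampling grid are rejected, mirroring the complete-records inclusion
criterion of the underlying study design.

## Synthetic cohort generator

Each patient's sign is a piecewise-linear skeleton alternating up/down
around a physiologic baseline (MAP 75 mmHg, HR 80 bpm, RR 16 /min,
TEMP 37.0 °C — clinically typical resting values; bounds 40–140, 30–190,
4–60, 34–42 in the respective units), resampled on the 10-minute grid with
additive Gaussian noise and clipped to the bounds.  Structural choices and
why:

- **Turning points** arrive as a Poisson process whose expected count over
  the reference window (8 h of collection ending 4 h before t0) is
  `extrema_count_mean`.  Turning times are snapped to the sampling grid:
  sub-grid dynamics are not modelled, so every nominal extremum is actually
  observed.  Without snapping, resampling attenuates peaks and the
  achievable min/median swing ratio falls structurally below the published
  control respiratory-rate value.
- **Overdispersion.**  The published trend-change-count group SDs (e.g.
  arterial pressure septic: mean 21.71, sd 8.48 — variance ≈ 72 against a
  Poisson variance of 22) are far beyond Poisson.  A per-patient gamma
  frailty (shape 4, mean 1) on the turning rate and a lognormal frailty
  (σ = 0.5, mean 1) on swing magnitude reproduce realistic across-patient
  spread; both default frailties can be switched off, recovering the pure
  truncated-Poisson/gamma model.
- **Swings** are gamma distributed (`swing_magnitude_mean`, `…_sd`):
  positive, right-skewed, two parameters — the published table provides
  only means and SDs.
- **Noise** is i.i.d. on the grid with sd defaulting to 1% of the mean
  swing, scaled by the patient's swing frailty.  Larger noise fractions
  generate spurious low-amplitude extrema in shallow segments, which both
  inflate `f1` above the published control/temperature level and collapse
  the minimal-intensity feature `f4`; 1% keeps measurement noise
  subordinate to physiologic swings at the scale the extraction sees.
- **Pre-onset ramp.**  Septic instability (rate and swing size) rises
  linearly over the last 6 h before t0 (`ramp_gain = 1`: doubled at t0).
  The temporal shape of pre-septic deterioration is not described by the
  source data, so the ramp is the simplest profile that makes the
  prediction-horizon sweep meaningful: windows further from t0 overlap less
  of the ramp and carry less signal.  Parameters are normalised so nominal
  values refer to the reference window regardless of ramp overlap.
- **Controls** have a flat profile; their reference moment t0 is placed at
  the end of the simulated stay (the study assigned it arbitrarily at
  ≥ 12 h after admission).  Signs are simulated independently — cross-sign
  correlation is not characterised by the published statistics and is not a
  calibration target.
- Stays up to 16 h are allowed (the horizon sweep needs 8 + 5 = 13 h of
  data).

### Calibration

`calibrate` matches the simulated group means of `f1` (count), `f3` (median
swing) and `f4` (min swing) per sign to supplied targets by damped
multiplicative updates of the turning rate, swing mean and swing sd, with
residuals standardised by the targets' standard errors (printed sd / √300).
Common random numbers (identical per-window seeds each iteration) make the
empirical moments smooth in the parameters; step sizes decay with the
iteration count because the min-swing response is steep enough to two-cycle
otherwise.  The shipped `default_params` are the frozen output of this fit
(seed 1, 400 windows per iteration, ≤ 60 iterations) against the published
group-statistics table; `calibrated_params()` regenerates them.

Residuals of the converged fit are below ~1 SE for all four model-input
features (MAP and RR trend-change counts, RR minimal swing, HR median
swing) in both groups.  One structural limit is worth knowing: the window
edge cuts the final swing at a roughly uniform phase, so the expected
minimal intensity cannot exceed about half the mean swing.  The control
arterial-pressure Min target (13.64 vs Median 21.14, ratio 0.65) is beyond
that cap and its calibrated mean settles ~1–4 SE low; it is not a model
input and does not affect the classification results.

## Feature selection, classifiers, evaluation

Importance is uniform across families — permutation importance with AUC
scoring, 20 repeats by default, rescaled so each model's best feature
scores 100 — rather than heterogeneous model-specific metrics, for
reproducibility across ecosystems.  Ties in the top-k ranking break
lexicographically.  On the calibrated synthetic cohort the strongest
separators are the arterial-pressure features (its count *and* intensity
contrasts are the largest in the published table), so the merged set does
not always equal the four features chosen in the original study; the
selection machinery recovers exactly that set when the signal is confined
to those columns, which is what the test suite asserts.

Classifiers are scikit-learn estimators behind thin wrappers: unpenalised
logistic regression; SVMs whose probabilities come from a sigmoid (Platt)
map fitted on out-of-fold decision values of the training set;
a single-hidden-layer MLP ("5 hidden layers" in the original report is read
as one hidden layer of 5 units, its toolkit's convention).  All pipelines
standardise features on training statistics.  The RBF kernel is
parameterised by its width σ, `K = exp(−d²/2σ²)`; the reported optimum
σ = 0.440227 was produced by a toolkit using `K = exp(−σd²)` and maps to
σ = 1/√(2·0.440227) ≈ 1.066 here (both values sit in the tuning grid, and
the mapped value is the default).  Tuning is stratified 10-fold CV
maximising mean AUC with ties to the least complex point.  The stratified
75/25 split preserves class counts exactly when they divide evenly
(600 balanced records → 450/150 at 225/225 + 75/75).

Evaluation: trapezoidal AUC over the empirical ROC (equivalent to the
Mann–Whitney statistic with mid-ranks); PR-AUC by trapezoid over the
precision-recall curve with the recall-0 endpoint set to the precision of
the most confident threshold; confusion metrics at the strict 0.5
threshold, with empty-denominator predictive values reported as NaN.  Group
comparisons use two-sided Welch t-tests — the published table reports
p-values without naming a test, and its uniform "<0.00001" entries (even
for near-identical group means) are not reproducible by any standard
two-sample test at n = 300/group, so p-values here are structural output,
not match targets.

## Problem sizes in the shipped checks

The test suite runs cohorts of 50–300 patients per arm: 300/group for the
calibration-closure and group-mean recovery checks (matching the reference
cohort size), 50/group × 20 seeds for the paired directional checks (longer
collection interval → higher AUC; variability features → higher AUC than
descriptive features), with logistic regression as the paired probe model.
These sizes give the directional comparisons clear majorities over seeds
while keeping the suite fast.

## What passing does and does not show

The generator reproduces group *means* of the extracted features, realistic
overdispersion, bounded physiologic ranges and a plausible pre-onset ramp.
It does not emulate: missingness and irregular sampling, cross-sign
coupling, integer quantisation of recorded values, circadian structure, or
treatment effects.  Synthetic class separation is consequently cleaner than
in real monitor data — held-out AUCs around 0.95 versus high-0.8s reported
on the EMR cohort — so passing results validate the pipeline's mechanics,
calibration and directional behaviour, not clinical performance.
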