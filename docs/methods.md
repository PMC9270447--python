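# Methods

This note documents the models and procedures implemented in `agebench`, the
design choices made where the design was genuinely open, and what the
synthetic scenarios do and do not show about real data.

## The deployment simulation

A dataset is a time-ordered table of records (timestamp, feature vector,
target), with timestamps converted to real-valued day offsets from the first
record (sub-day resolution kept as fractional days). All windows are
half-open `[start, end)` so adjacent windows partition records exactly.

One deployment instance is defined by a deployment time t₀ and a model age
dT, with three derived windows:

| window | interval | role |
|---|---|---|
| train | [t₀ − 365, t₀ − 30) | model fitting |
| holdout | [t₀ − 30, t₀) | MSE(t₀) — training-time error |
| future | [t₀ + dT, t₀ + dT + 30) | MSE(t₀ + dT) — error at age dT |

and the outcome is E_rel(dT) = MSE(t₀ + dT) / MSE(t₀).

Windows are fixed **durations**, not fixed record counts: that keeps the
day-denominated dT axis exact on multi-record-per-day data, with a
minimum-record guard (50) protecting error comparability; a draw whose train
window is under the guard is rejected and redrawn so the instance count
stays exact (a rejection rate above 20% aborts with a data-density error).
The future test-set duration (30 days) is a design choice balancing MSE
estimation variance (≈150 records per window at 5 records/day) against the
temporal resolution of the aging curve. The training-time holdout is the
final 30 days of the history year — a chronological holdout mirrors how
deployment-time validation is actually done, and makes E_rel(dT ≈ 0) ≈ 1 a
meaningful calibration check. dT starts at −14 days so that the youngest
models have test sets touching or slightly overlapping their holdout.

t₀ ~ Uniform(start + 365, end − dT_max − 30) and
dT ~ Uniform(−14, dT_max) independently, with dT_max capped at half the
dataset span. The buffers guarantee every admissible pair yields fully
in-range windows, which is what makes the two marginals independently
uniform (checked by KS tests and the empirical correlation in the suite).

Degenerate instances with MSE(t₀) = 0 are excluded and counted rather than
clamped — E_rel is undefined there and clamping would distort percentile
curves.

## Models

Four families behind one contract — ridge regression (RV), random forest
(RF), gradient boosting (XG, via xgboost), multilayer perceptron (NN, via
scikit-learn):

- Features are standardized with center/scale computed on the training
  window only; the scaler travels with the fitted model. Zero-variance
  features are dropped with a warning and recorded.
- Every stochastic fit takes an explicit seed; identical (family,
  hyperparameters, data, seed) reproduces bit-identical predictions. Per
  instance, the seed is `plan_seed XOR instance_index` (kept below 2³¹).
- Hyperparameters come from exhaustive grid search with chronological
  expanding-window cross-validation (`TimeSeriesSplit`, 5 folds): fit on
  blocks 1..k, validate on block k+1; selection minimizes mean validation
  MSE with ties broken toward the simpler model (fewer/smaller trees or
  layers, larger penalty). Default grids ship as an in-package YAML and are
  fully overridable. In a suite, tuning is refreshed once per contiguous
  batch of 100 instances (sorted by t₀), anchored at the training window of
  the batch's median-t₀ instance; a failed tuning falls back to the previous
  batch's values with a warning.
- The deployment-quality gate is pooled chronological-CV
  R² = 1 − SSE/SST over validation folds, with a 0.7–0.9 acceptance band:
  models of realistic quality — good enough to deploy, not so good that the
  task is trivial. A lower-bound-only mode is available.
- Non-converged network fits are kept but flagged; discarding them would
  bias the aging distribution.

**Feature importance.** The linear family reports signed standardized
coefficients, so sign flips in the underlying process are visible. The
nonlinear families report permutation importance (mean MSE increase over 10
seeded shuffles, floored at zero) — a model-agnostic measure comparable
across families. Vectors are L2-normalized; an all-zero vector (e.g. from a
constant-target fit) is returned un-normalized.

## Aging statistics

**Moving percentiles.** For grid points spaced bandwidth/2 apart (bandwidth
default 5% of the dT range), the 25th/50th/75th empirical percentiles
(linear interpolation) of E_rel among instances within ±bandwidth/2 of the
grid point. Bins with fewer than 20 members are omitted — which is also why
the periodicity analysis uses Lomb–Scargle rather than an FFT: the reported
grid may be uneven.

**P_ac.** Per fixed 30-day bin, the fraction of instances with E_rel
strictly below 2.0 (an instance exactly at the threshold is *not* accurate).

**Pattern classification.** The taxonomy — stable, gradual, explosive,
increasing unpredictability — is qualitative in origin; the numeric rules
here are this package's operationalization, all thresholds configurable and
reported as evidence alongside the label:

1. explosive: peak median ≥ 5× the early-bins median *and* the excess is
   concentrated after a changepoint (single-changepoint binary segmentation;
   post/pre mean ratio ≥ 3);
2. else gradual: positive Theil–Sen median trend with late median ≥ 1.5× the
   early median;
3. else variability growth: late IQR ≥ 2× early IQR with positive IQR trend;
4. else stable.

"Early"/"late" are medians over the first/last quartile of reported bins.
All rules are ratios and slope signs, so the label is invariant to
stretching the time axis.

**Periodicity.** A robust (Theil–Sen) line is removed from the median curve,
then a Lomb–Scargle periodogram is evaluated on 400 periods over 30–500 days
(clipped with a warning to span/1.5 for short curves). Significance is the
permutation p-value of the maximum in-range power over 500 seeded shuffles
of the detrended bin values; a dominant period is only reported when
p < 0.05.

## Dynamics

Phase portraits are built from models *refit per sliding window* (default 90
days, step 30), independent of the randomized suite — the two analyses
answer different questions. Per-window normalized importance vectors are
column-centered and projected by SVD onto the first two principal
components (sign convention: each loading's largest-magnitude entry is
positive; PCA is taken on normalized importances, matching how the vectors
are reported). States are k-means clusters (10 seeded restarts) on the 2-D
scores, with k chosen in 2..6 by silhouette; dwell time is step-days per
assigned window.

Error attractors are modes of a product-Gaussian kernel density estimate
over (dT, log E_rel) — the log because explosive errors span decades — with
per-axis Silverman bandwidths on an 80×80 grid. Modes are grid local maxima
with density ≥ 2× the median grid density (the operationalization of a
"dense basin"; configurable); each mode's mass fraction is the density
integral over its watershed basin, normalized so basin masses plus
unassigned mass sum to 1.

## Synthetic scenarios

All scenarios share: 5-year span, 5 records/day with uniform intra-day
jitter, 5 i.i.d. standard-normal features, target
y(t) = β(t)·x + s(t) + ε(t). Features are stationary **by design**: all
temporal structure flows through coefficients, the latent seasonal term, or
the noise process. That isolates model aging in the absence of feature
drift — the regime where degradation is hardest to anticipate — and is the
main idealization: real operational data also drift in their feature
distributions, contain gaps and regime-dependent sampling, and their
"truth" is unknown. Passing the recovery tests shows the bench detects the
structure it targets, not that any real dataset is exhausted by these
structures.

Calibration choices (chosen once, by analysis of the generator):

- `noise_sd` defaults to the value giving analytic
  R² = Var(βx)/(Var(βx)+σ²) = 0.8 with β = (2, 1, 0.5, 0, 0) — the middle of
  the deployment-quality band.
- `coefficient_drift` adds 8×10⁻⁴/day to every coefficient: over the
  maximum model age (~2.5 years) the coefficient displacement stays
  comparable to the noise scale, so E_rel grows at most linearly — the
  gradual regime, not an explosive one.
- `seasonal_latent` adds an *unobserved* sinusoid (amplitude 3× noise SD,
  period 365 d) to the target only; it never enters the feature matrix.
- `regime_switch` negates all coefficients at mid-span, producing both an
  explosive error escalation for deployments that cross the switch and an
  importance sign flip for the phase portrait.
- `variance_growth` multiplies the noise SD by 2 during high-volatility
  episodes (30-day slots) whose rate ramps linearly from zero at mid-span,
  capped at a quarter of slots, so the *expected* noise variance grows
  while the median stays put: the median E_rel remains ≈ 1 and the 25–75
  gap widens with age — increasing unpredictability rather than gradual
  median growth, which is the defining feature of that pattern. Episodes
  are placed by systematic (cumulative-rate) sampling with a seeded random
  phase so the realized burst count tracks the intended schedule in every
  realization; a plain Bernoulli draw can produce realizations with
  essentially no variance growth at all, i.e. scenarios that contradict
  their own labels.

`expected_pattern` maps each scenario to the behavior it was built to show
(stationary → stable, drift → gradual, switch → explosive, variance growth →
variability growth, seasonal → period 365 d), giving every end-to-end test a
ground truth.

## Data screening

Datasets for degradation suites must span ≥ 730 days (configurable) and
contain no missing values (missing data is rejected, not imputed — the
bench studies aging, not imputation behavior). An abrupt-change heuristic
flags any day where the 7-day average of daily target means jumps, relative
to the preceding 7-day average, by more than 6 robust SDs of the daily
means (scale from median absolute day-to-day differences, so a level shift
cannot inflate its own detection threshold). There is no standard
quantitative definition of "abrupt" here; this rule is the package's own
operationalization and is a warning, not a hard gate — abrupt-change
screening is a data-selection concern, not an algorithmic step.

## Numerical and reproducibility notes

- Results CSVs are written with `%.17g` and read with round-trip float
  parsing: export → import is bit-exact, and identical (config, seed) runs
  produce byte-identical CSVs (checked via SHA-256 manifests).
- SVG figures are rendered with a fixed hash salt and no embedded date, so
  re-rendering unchanged inputs is byte-stable.
- Default problem sizes (n = 300–800 instances for calibration and
  seasonality runs, n = 500 per seed for pattern recovery, 80×80 KDE grids,
  400-period periodograms, 500 permutations) keep a full suite-plus-
  diagnostics run in the seconds-to-minutes range on one CPU while leaving
  per-bin counts (≥ 20) and test power comfortable; all are parameters.

## Known limitations

- The pattern-classifier thresholds (5×, 3×, 1.5×, 2×) are heuristics
  validated against the synthetic scenarios, not fitted to any real-world
  corpus; borderline curves near a threshold can flip labels.
- Periodicity detection assumes one dominant cycle after linear detrending;
  nested or amplitude-modulated cycles are reported only by their strongest
  component.
- Permutation importance is computed on the fitting window (in-sample);
  with heavily overfit nonlinear models it can understate irrelevant-feature
  noise.
- The engine retrains a model per instance; it does not emulate online or
  continuous retraining of a single persistent model, and no forecasting of
  E_rel beyond the observed dT range is attempted.
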