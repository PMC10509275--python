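# Methods

## Scratch power as ground truth

Scratch intensity is defined mechanically: the mean contact force (N)
times the mean contact speed (mm/s) of the scratching finger over a 1-s
window, giving milliwatts on a 0–600 mW scale. Force comes directly
from the tablet's contact stream, discarding no-contact (NaN) samples.
Velocity is geometric: the y trajectory is linearly interpolated across
contact gaps, smoothed with a Savitzky–Golay filter (polynomial order 5,
window 31 samples = 0.21 s at 150 Hz), and its peaks and valleys —
stroke turnarounds, where finger velocity changes sign — segment the
motion into strokes. Mean velocity is the unweighted mean over adjacent
turnaround pairs of Euclidean chord length divided by elapsed time;
with `q` turnarounds in a window that is a mean over `q − 1` strokes.

Two implementation choices matter and are deliberate:

* **Turnaround locations vs. amplitudes.** Turnarounds are *detected*
  on the smoothed trajectory (detection needs noise suppression), but
  chord positions are *read* from the interpolated, unsmoothed series
  at the detected timesteps. The 0.21-s smoothing window rounds stroke
  corners; reading amplitudes from the smoothed series biases chord
  lengths — and hence velocity and power — low by roughly 15% at 3 Hz
  and 24% at 6 Hz scratching. With amplitudes from the interpolated
  series the bias stays under ~4% across 1–6 Hz (under ~8% with
  lift-off gaps), verified against analytic triangle-wave scratches.
* **Peak-finder parameters.** Minimum turnaround separation 0.05 s
  (admits up to 10 Hz scratching, beyond observed human rates) and
  minimum prominence 1.0 mm. The prominence floor exists because
  interpolation across lift-off gaps produces plateaus whose position
  noise otherwise spawns micro-peaks with near-zero chords, collapsing
  the velocity mean at low stroke rates. 1.0 mm is far below any
  plausible stroke amplitude (≥5 mm) and well above position noise
  (~0.2 mm). Both are configurable in `find_critical_points` /
  `label_stream`.

Windows are half-open `[t0, t0 + 1 s)` so boundary turnarounds are
counted once. Smoothing and turnaround detection run once per recorded
block; windows are cut afterwards. Outlier filters reject a window when
(1) it has fewer than 2 turnarounds, (2) two consecutive turnarounds
have the same kind (a missed stroke), (3) any consecutive-timestep
change in interpolated x or y exceeds 5 mm (tracking glitch), or
(4) power exceeds 600 mW (infeasible for scratching). Rejected windows
are retained with their reason; windows with no contact at all are
tagged `no_contact`. Filters are checked in that order, so a window
failing several reports the first.

## Spectral features

Wearable windows are 1 s with 0.25-s stride, fully contained in the
recording (`floor((T − 1)/0.25) + 1` windows). Gaps are linearly
interpolated per channel; windows within ±2 samples of nominal length
(8000 mic / 400 acc) are linearly resampled onto the nominal grid,
larger deviations are rejected. Features are single-sided DFT
amplitudes `(2/N)|DFT(signal)|` with the `2/N` factor applied to every
retained bin including DC; bin `k` of a 1-s window is exactly `k` Hz.
No tapering or zero-padding is applied, and the accelerometer z axis is
used without detrending. Retained bins: intensity task mic 0–399 Hz +
acc 0–174 Hz (575 features); detection task mic 0–274 Hz + acc
0–199 Hz (475 features), microphone block first. Min–max normalization
is fitted on training data only; constant features map to 0; test
values are transformed affinely and may leave [0, 1].

## Networks

Both models are fully connected ReLU networks trained with Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch 64, 150 epochs, per-epoch
shuffling, inverted dropout on each hidden layer, He-normal
initialization; all randomness flows from one seed, and training is
bit-reproducible on a machine. Intensity: 2 hidden layers × 1000,
dropout 0.1, MAE loss, learning rate 5·10⁻⁶, linear output in mW.
Detection: 3 × 1200, dropout 0.2, BCE loss through a sigmoid output,
learning rate 1·10⁻⁵; the decision threshold is 0.5 with ties called
positive. Predictions are *not* clipped when computing metrics; an
explicit flag clips intensity output to [0, 600] for display on the
clinical scale.

For the small synthetic cohorts used in the test suite the full recipe
is disproportionate: at learning rate 5·10⁻⁶ the Adam update moves each
parameter by at most ≈ lr per step, so a few epochs on a few thousand
samples cannot move the output head from its ~0 mW initialization to
the 100+ mW label range. `models.reduced_config` therefore keeps the
architectures and shrinks the schedule (intensity: 10 epochs at 10⁻³;
detection: 1 epoch at 10⁻³), which reaches the regime the full recipe
reaches on the full-scale recorded data. The model-capacity check uses
batch 16 and no dropout, again at the published width/depth.

## Evaluation

LOSO-CV: one fold per participant; scaler and model are fitted per fold
on the training participants only (each fold's report records the
training-set identity of its scaler, so leakage is checkable after the
fact). Aggregates are unweighted mean ± sd across folds. MAE is the plain
mean absolute error in mW; MAPE is MAE normalized by the 600 mW
scale maximum × 100 — *not* per-sample percentage error — so
MAPE ≡ MAE/6 identically. Detection reports percent accuracy overall
and per interaction (computed per fold, averaged across folds).
Modality ablations (mic-only / acc-only) slice the feature matrix and
flow through the identical scaler + model pipeline.

Validation-study analyses: per instructed level 1–5, group means and
two-sided paired Wilcoxon signed-rank tests between adjacent levels
(zeros dropped; exact null for n ≤ 25, normal approximation above;
identical groups report p = 1). The pooled Spearman correlation
min–max-normalizes each participant-set's five level means (constant
sets are excluded with a warning) before correlating level against
normalized value. Per-participant scales are ordinary least-squares
lines of ground-truth mW against instructed scale value; the ideal
0→0 mW, 10→600 mW mapping has slope 60 mW/unit and intercept 0.
Conversion to the 0–10 scale is linear `p/60` by default; the square-
root alternative is `10·√(p/600)` (one of several maps fixing the 0 and
600 mW endpoints; the choice is configurable and documented as an
assumption). Headline numbers are rounded to 2 decimals in reports; raw
values are preserved.

## Synthetic data: what it emulates, and what it does not

`ScratchSpec` builds 150 Hz tablet streams: triangle (constant-speed)
or sinusoid strokes of amplitude A (half peak-to-peak) at f stroke
pairs per second, so the chord-based estimator's target velocity is
exactly 4·A·f; force is Gaussian around its mean; position noise is
Gaussian (default 0.2 mm). `lift_fraction` models contact loss at
turnarounds: the finger dwells at the stroke extremum while the sensor
reports no contact, so interpolation reconstructs a plateau at ±A. (A
model in which the gap masks the turnaround excursion itself would bias
the estimator low by roughly the lifted fraction; the dwell model
matches the estimator's ~8% recovery error at 30% lift.) Parameters
implying per-timestep motion above the 5 mm jump filter emit a warning
— such streams are *intended* to be rejected and exist for filter
tests.

Wearable signals are band-limited Gaussian noise shaped in the
frequency domain. Scratch activity places energy at 120–460 Hz
(microphone) and 70–180 Hz (accelerometer) with per-bin amplitude
linear in power × a per-participant gain (lognormal, sd 0.15 — the
inter-subject variation that makes LOSO meaningful), plus a
power-independent low-frequency arm-motion band. Per-second lognormal
envelope jitter (mic sd 0.22, acc sd 0.14) limits single-modality
regression accuracy, with the microphone noisier than the
accelerometer. Non-scratch activities draw from distinct envelope
families; deliberately, table tapping and clapping reuse the scratch
*microphone* envelope and air scratching reuses the scratch
*accelerometer* envelope, so each single modality is blind to specific
confusers and multimodal fusion has measurable headroom — the
qualitative structure of the recorded ablation results.

Cohort defaults mirror the recorded study designs: intensity = 9
instructed force × speed blocks (forces {0.25, 0.6, 1.2} N, stroke
speeds {80, 180, 320} mm/s via (A, f) ∈ {(10, 2), (15, 3), (20, 4)},
with per-participant jitter and per-block lift 0 or 0.2) of 10 s per
participant; detection = 14 activities (7 scratch sites, 7 non-scratch)
× 30 s per participant; validation = 5 instructed levels × 2 sets per
participant with level means {95, 130, 170, 205, 260} mW and
multiplicative per-participant scale interpretation. Intensity labels
for training come from running the actual labeling algorithm on the
synthetic tablet streams, not from the generator's truth record.

What passing tests on this cohort show: the pipeline's algebra and
plumbing are correct end to end — labels recover programmed power,
features order by power, models learn, folds don't leak, ablations
order sensibly. What they do not show: performance on real skin
vibration. The generator makes no claim of physical fidelity (no
resonances, no sensor nonlinearity, no motion artifacts, no
inter-activity variability within a participant), and its absolute MAE
numbers are not comparable to values measured on recorded human data.

## Numerical choices and degenerate inputs

All-missing force windows reject as `no_contact`; fewer than two
contact samples make interpolation (and the block) unlabelable; series
shorter than 31 samples cannot be smoothed. A constant training feature
normalizes to 0 rather than dividing by zero. Empty training sets and
dimension mismatches raise; a single-class detection training set warns
and proceeds. Sampling-rate metadata within 1% of nominal is accepted
with a warning, beyond that rejected. Aggregate statistics ignore NaN
fold metrics (e.g. rank correlation of a degenerate fold). Model
archives store weights, config, scaler parameters and the loss curve.

## Problem sizes in the test suite

The shipped suite runs the full LOSO evaluation on the default
10-participant cohort (≈3,300 intensity windows × 575 features;
16,380 detection windows × 475 features) for the combined model and
both single-modality ablations, with `reduced_config` schedules; the
whole suite completes in roughly 10–12 minutes on one CPU core. The
capacity and learnability unit tests use narrower networks (width
16–32) where the published width is not itself under test.

## Known limitations

* The velocity estimator assumes a single contact; multi-touch
  scratching is out of scope.
* The unweighted mean of per-stroke speeds weights short and long
  strokes equally; for strongly irregular stroke timing a
  time-weighted mean would differ.
* The square-root scale map's exact published form is not recoverable
  from its reported error alone; the implemented form is one endpoint-
  preserving choice.
* The released-dataset adapter supports the layout documented in
  `cli_io.zenodo_adapter`; other deposit layouts raise
  `UnsupportedLayoutError` rather than guessing.
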