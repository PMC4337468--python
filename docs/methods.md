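# Methods

This note records the models the package implements, the defaults it
chooses where the underlying study design leaves them open, and what the
synthetic experiments do and do not demonstrate.

## Sensor model and calibration

A tri-axial accelerometer with per-axis null shift `o` (g) and scale
factor `s` (dimensionless) reports `raw = s·a + o` for true acceleration
`a`; cross-axis coupling (sensor misalignment) is deliberately not
modelled, matching the axis-aligned-ellipsoid error description the
pairwise-ellipse procedure assumes. Static tumble orientations therefore
lie on an ellipsoid with centre `o` and semi-axes `s`.

`fit_ellipse_pair` fits the axis-aligned conic `a·u² + b·v² + c·u + d·v =
1` by linear least squares and reads off centre `(−c/2a, −d/2b)` and
semi-axes. Applied naively to a pair of axes of whole-sphere tumble data
the fit is biased, because points away from the pair's great circle
project *inside* the ellipse. `fit_calibration` therefore iterates:
calibrate with the current estimate, refit each pair with a per-point
target radius² of `1 − w²` (where `w` is the calibrated third-axis
component, so each point is compared against the circle it should lie on),
combine per axis as the arithmetic mean of the two pairwise estimates, and
repeat to convergence. Two numerical details matter:

* with a varying right-hand side the conic's constant term is
  identifiable and must be fit explicitly (five coefficients, not four);
* the all-axes common-scale mode is only weakly identified — inflating
  every scale is almost exactly compensated by the shrunken third-axis
  correction — so each iteration re-normalises the scales to make the
  calibrated tumble samples average 1 g. With the gauge fixed the
  iteration converges in ~35 steps; without it the scales drift.

Noise-free recovery is exact to ~1e-14; at a realistic tumble noise of
0.005 g, 500 orientations recover offsets and scales to ~1e-3. A
sphere-coverage diagnostic (≥3 points per octant of the centred cloud,
configurable) rejects one-sided tumbles before fitting, since the
least-squares ellipses extrapolate badly outside the sampled arc.

## Windowing and predictors

Windows are 2 s, non-overlapping, trailing partial windows dropped. The
static component is the per-window mean (rather than a running mean):
windows become exactly independent, and for behaviors that are stationary
over 2 s the difference is second order. The magnitude-based predictors
(`Amp_M`, `DF_M`, `SD_M`) are computed on the mean-subtracted magnitude of
the *dynamic* signal; the window's `mag_range` used for predation
screening is max − min of the *calibrated* (gravity-included) magnitude,
because screening operates on raw movement violence, not on the
posture-removed residual.

Spectra use the real FFT of the mean-removed signal with the DC bin
excluded; amplitude is normalised as `2|X_k|/n` so a unit sinusoid at a
bin frequency reports 1 g, and ties (including the all-zero signal) break
deterministically to the lowest frequency, i.e. 0.5 Hz for 2-s windows.
`DF` is therefore always in (0, fs/2].

Downsampling is plain decimation (every `fs/target`-th sample, no
anti-alias filter): it mirrors what a sensor simply sampling slower
records, is exactly reproducible, and keeps bin-aligned tones below
Nyquist intact. A low-pass variant (`antialias=True`, scipy's `decimate`)
is provided for comparison but is not the default.

## Forests

Both classifiers use 500 trees, each grown on an independent random
subsample of 1000 windows drawn **without replacement** (realised as a
bagging ensemble with `bootstrap=False` over decision trees with
`max_features=5`), prediction by majority vote with a seeded random
tie-break. The subsample is per tree; when fewer than 1000 training rows
exist each tree sees all of them (logged). These are classical
classification forests with marginal permutation importance (mean
held-out accuracy drop over seeded column shuffles, ties stable in column
order), not conditional-inference forests: on synthetic data the
predictor correlation structure is controlled by design, which removes
the bias the conditional variants guard against.

Evaluation uses a stratified 70/30 window split with a fixed seed; in the
downsampling experiment the split is computed once on the 64-Hz windows
and shared across frequencies (windows correspond one-to-one), so the
frequency effect is not confounded with split noise.

## Synthetic generator

Each behavior class is parameterised by a dominant frequency, a heave
amplitude, a per-axis noise SD, a posture pitch (orienting the static
gravity vector) and a commanded ground speed:

| class      | f (Hz) | A (g) | noise SD (g) | speed (m/s) |
|------------|-------:|------:|-------------:|------------:|
| rest       | 0      | 0     | 0.05         | 0           |
| groom      | 0.5    | 0.1   | 0.12         | 0           |
| feed       | 1.0    | 0.2   | 0.15         | 0           |
| low_move   | 1.5    | 0.5   | 0.10         | 0.8         |
| high_move  | 3.0    | 1.5   | 0.15         | 3.0         |

The heave axis carries `A·sin(2πft)`; oscillating classes add a
quadrature surge component at half amplitude. These values are this
package's design choices, picked so the classes are separable but not
degenerate and so locomotion shows footfall-like periodicity; they are
**not** estimates of puma kinematics, and the observed near-perfect
synthetic classification accuracies measure pipeline correctness, not
expected field performance. Real captive data include transition noise,
postural variety within behaviors, and overlapping spectral signatures
(feeding vs grooming) that the generator only hints at via its noise
floors — which is why the published behavior-model difficulties with feed
and groom are reproduced qualitatively at best. Behavior transitions are
instantaneous by construction; transition windows are not modelled.

GPS tracks integrate a correlated random walk: one step per 2-s window at
the commanded speed, heading diffusing with SD 0.03 rad per window so the
heading stays correlated for longer than a 15-min fix interval and
inter-fix displacement scales roughly linearly with the interval's mobile
fraction; fixes get isotropic positional noise of SD 10 m. Injected
predation bursts fill whole 2-s windows with a 3–6-Hz oscillation of
amplitude equal to the requested magnitude, which guarantees a
within-window magnitude range exceeding it on a quiet ~1-g background.

## Activity budgets and GPS validation

Budgets pool windows by clock hour of the window start across days;
hours without data are flagged, never zero-filled, and an across-day SD
accompanies each pooled proportion. Step lengths are haversine distances
on the WGS84 mean radius (6,371,008.8 m); a planar mode serves synthetic
tracks. Intervals with less than 80% prediction coverage are dropped and
logged. The validation model is `distance_m ~ percent_mobile` with a
random intercept per individual, fit by REML (statsmodels MixedLM);
singular fits (random-intercept variance on the boundary, expected when
synthetic individuals share one generator) are reported in the result
object, never silently dropped. The synthetic validation study uses 4
individuals × 6 h at 15-min fixes (~92 steps), generated at 8 Hz — the
mixed model consumes only labels and positions, so the accelerometer
sampling rate is immaterial there and a lower rate keeps the simulation
cheap.

## Predation screening

The high-acceleration threshold is mean + 2 SD of an individual's
per-window magnitude ranges, single pass (no iterative re-exclusion of
flagged windows), with a fixed override (canonically 3.4 g) available.
The detection experiments use the fixed override: by construction the
adaptive mean+2SD rule flags ~2% of windows on *any* record, so a
zero-false-positive expectation is only meaningful against an absolute
threshold. Clusters are maximal runs of flagged windows with successive
gaps ≤180 s, at least 2 members; size is the flagged-window count and the
duration is reported alongside. Percentiles use max-rank (ties share the
higher percentile) and the top-10% flag requires a percentile strictly
above 90, so exactly one of ten distinct values is flagged while a full
tie flags everything. Feeding events span from 4 h before the first
kill-site fix to the last fix; overlap is tested against
`[event_start − one GPS interval, end of first quartile]`, with the
interval taken from the cadence active at the event (900 s intensive,
14,400 s standard).

## Problem sizes and determinism

The bundled experiments use 2000-window datasets (≈67 min at 64 Hz) for
classification, 100 seeded replicates for detection and mixed-model
studies, and 500 tumble orientations for calibration — sizes at which all
Monte-Carlo bands in the tests are comfortably wide. Every stochastic
path flows through `numpy.random.default_rng` seeds; identical seeds give
bit-identical datasets, predictions and output files.

## Known limitations

* The generator's class geometry is idealised; field performance claims
  require real training data.
* No gyroscope/magnetometer fusion, temperature drift, or cross-axis
  misalignment in the sensor model.
* Decimation without filtering aliases any energy above the target
  Nyquist; the generator's band-limited signals are benign, real data may
  not be.
* The behavior taxonomy is fixed at five classes; transition windows and
  mixed-behavior windows are out of scope.
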