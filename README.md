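# collarmotion

Behavior classification, activity budgets and predation screening from
tri-axial accelerometer collars on free-ranging terrestrial carnivores.

Large felids are cryptic: GPS fixes every few hours say where an animal
went, but not what it did. A collar-mounted accelerometer sampling at 64 Hz
records body movement continuously, and behaviors observed on captive
animals can train a classifier that is then applied to wild individuals.
`collarmotion` implements that pipeline end to end:

1. **Calibration** — tumble data (the collar held in many static
   orientations) should trace the unit-g sphere; null-shift and per-axis
   scale-factor errors turn it into an off-center, axis-aligned ellipsoid.
   Ellipses fit two axes at a time recover per-axis offset `o_i` and scale
   `s_i`, and raw output maps to units of g as `a_i = (raw_i − o_i)/s_i`.
2. **Features** — calibrated traces are cut into 2-s windows; the
   within-window mean (static, gravity/posture) is subtracted leaving the
   dynamic signal `d`. Sixteen predictors per window: per-axis
   `ODBA_i = mean|d_i|` and their sum ODBA; the dominant FFT frequency
   `DF` and its amplitude `Amp` for each axis and for the dynamic
   magnitude (DC excluded, 0.5-Hz resolution); and the standard deviations
   `SD` of each axis and of the magnitude.
3. **Classification** — random forests with a fixed recipe: 500 trees,
   each grown on a random subsample of 1000 windows drawn without
   replacement, 5 candidate predictors per split, majority vote with
   random tie-break. A 2-class mobility model (mobile vs non-mobile) and a
   5-class behavior model (rest, feed, groom, low-/high-acceleration
   movement). A downsampling experiment retrains the mobility model at
   32/16/8/4/2 Hz.
4. **Ethogram + GPS validation** — predictions aggregate to 24-h activity
   budgets (proportion of windows mobile per clock hour); over each
   inter-fix GPS interval the percent of time predicted mobile is
   regressed on the step length with a linear mixed model,
   `distance ~ percent_mobile + (1 | individual)`.
5. **Predation screening** — windows whose acceleration-magnitude range
   exceeds a threshold (mean + 2 SD per individual, canonically ≈3.4 g)
   are grouped into clusters (≥2 flagged windows, gaps ≤3 min), ranked by
   size and maximum magnitude, and matched against GPS-derived feeding
   events (kill-site fix span plus the preceding 4-h interval; a cluster
   supports a kill when it falls between one GPS interval before the event
   start and the end of its first quartile).

No field data ship with the package. A synthetic generator
(`collarmotion.synthetic`) produces labeled 64-Hz traces with
behavior-specific dominant frequencies and amplitudes, GPS tracks whose
step lengths covary with mobility, sensor miscalibration, and injected
attack bursts — so the whole pipeline is testable and reproducible from a
seed.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data, writing tables to `results/`:

```sh
python analysis/01_simulate_collar_data.py 1   # seed 1
python analysis/02_calibrate.py
python analysis/03_extract_features.py
python analysis/04_train_models.py 1
python analysis/05_downsampling.py 1
python analysis/06_activity_validation.py 1
python analysis/07_predation_screen.py
```

With seed 1 the calibration stage recovers the injected sensor errors to
better than 0.001:

```
fitted: {'offset_x': 0.0802, 'offset_y': -0.1193, ..., 'scale_z': 1.0291}
truth:  {'offset_x': 0.08,   'offset_y': -0.12,   ..., 'scale_z': 1.03}
max |offset error| = 0.0007 g
max |scale error|  = 0.0009
```

the feature medians separate the classes (rest ODBA 0.12 g vs
high-acceleration movement 1.56 g; walking DF_Z 1.5 Hz, running 3 Hz), the
mobility model classifies held-out windows at 100% (the synthetic classes
are cleanly separable; accuracy stays ≥99% down to 2 Hz), the mixed model
recovers a strongly positive mobility-distance slope
(17.9 m per % mobile, SE 1.9, p ≈ 1e-20 across 4 individuals × 92 steps),
and the predation screen finds exactly the injected attack cluster:

```
size  duration_s  max_mag_range  top10_size  top10_magnitude  overlaps_feeding_event
   5       242.0           4.83        True             True                    True
```

The same stages are available as a CLI (`collarmotion simulate|calibrate|
featurize|train|evaluate|importance|downsample-exp|predict|budget|
predation|validate|run-all`) for CSV inputs from real collars.

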