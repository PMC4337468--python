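"""Reusable synthetic experiments: the captive-analog classification study,
the downsampling study, predation-detection replicates and the GPS
mixed-model validation study.

Each function is deterministic given its seed and returns plain numbers or
small tables, so the analysis drivers, the test suite and the acceptance
script all run the same computations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, ethogram, predation, synthetic
from .features import downsample, features_frame
from .synthetic import Schedule

#: class mix echoing the captive training data's imbalance
#: (rest-heavy, few high-acceleration bouts)
IMBALANCED_WEIGHTS = {
    "rest": 0.545, "feed": 0.133, "groom": 0.036, "low_move": 0.263, "high_move": 0.023,
}


def imbalanced_schedule(total_s: float, seed: int) -> Schedule:
    """Random bout schedule with the captive-style class imbalance."""
    rng = np.random.default_rng(seed)
    labels = list(IMBALANCED_WEIGHTS)
    p = np.array(list(IMBALANCED_WEIGHTS.values()))
    entries: list[tuple[str, float]] = []
    remaining = int(round(total_s / 2.0))
    while remaining > 0:
        label = labels[rng.choice(len(labels), p=p)]
        nwin = min(1 + rng.geometric(2.0 / 30.0), remaining)
        entries.append((label, nwin * 2.0))
        remaining -= nwin
    return Schedule(entries)


def mobility_accuracy(
    seed: int,
    duration_s: float = 4000.0,
    freqs: tuple[float, ...] = (64, 16),
    test_size: float = 0.3,
) -> dict[float, float]:
    """Held-out mobility-model accuracy (%) per sampling frequency.

    One synthetic dataset (>= duration/2 windows, balanced bout schedule) is
    generated at 64 Hz, decimated to each requested frequency, features are
    re-extracted, and a forest with the standard recipe is trained and
    evaluated on one stratified 70/30 window split shared across
    frequencies.
    """
    sched = Schedule.uniform_random(duration_s, seed=seed)
    ds = synthetic.gen_dataset(sched, fs=64, seed=seed)
    y = classify.mobility_labels(ds.true_labels["behavior"])
    tr, te = classify.train_test_split_indices(y, test_size, seed=seed)
    out: dict[float, float] = {}
    for fs in freqs:
        feats = features_frame(downsample(ds.trace, fs))
        model = classify.train(feats.iloc[tr], y[tr], task="mobility", seed=seed)
        out[fs] = classify.evaluate(model, feats.iloc[te], y[te]).overall_accuracy
    return out


def behavior_confusion(
    seed: int, duration_s: float = 4000.0, test_size: float = 0.3
) -> classify.ConfusionMatrix:
    """Five-class behavior model on an imbalanced captive-style dataset."""
    sched = imbalanced_schedule(duration_s, seed=seed)
    ds = synthetic.gen_dataset(sched, fs=64, seed=seed)
    feats = features_frame(ds.trace)
    y = ds.true_labels["behavior"].to_numpy()
    tr, te = classify.train_test_split_indices(y, test_size, seed=seed)
    model = classify.train(feats.iloc[tr], y[tr], task="behavior", seed=seed)
    return classify.evaluate(model, feats.iloc[te], y[te])


def predation_detection_replicate(
    seed: int,
    n_bursts: int = 4,
    burst_magnitude: float = 4.0,
    background_s: float = 3600.0,
    fs: float = 64,
    threshold: float = predation.DEFAULT_THRESHOLD_G,
) -> dict:
    """One detection replicate: quiet trace + injected attack cluster.

    Returns whether an overlapping cluster was detected and whether it was
    top-10%-flagged for both size and magnitude, plus the cluster count on
    the burst-free version of the same trace (the false-positive control).
    """
    sched = Schedule(
        [("rest", background_s / 2), ("low_move", background_s / 4), ("rest", background_s / 4)]
    )
    ds = synthetic.gen_dataset(sched, fs=fs, seed=seed)
    at = background_s / 2
    burst_trace, bursts = synthetic.inject_predation(
        ds.trace, at=at, n_bursts=n_bursts, burst_magnitude=burst_magnitude,
        gap=60.0, seed=seed,
    )

    def clusters_of(trace):
        feats = features_frame(trace)
        mr = feats["mag_range"].to_numpy()
        thr = predation.high_acc_threshold(mr, override=threshold)
        return feats, predation.find_clusters(feats["window_start"], mr > thr, mr)

    _, control = clusters_of(ds.trace)
    feats, clusters = clusters_of(burst_trace)
    detected, flagged = False, False
    if clusters:
        predation.rank_clusters(clusters)
        t_inject = ds.trace.t0 + pd.Timedelta(seconds=at)
        for c in clusters:
            if c.end >= t_inject and c.start <= t_inject + pd.Timedelta(seconds=n_bursts * 60.0):
                detected = c.size >= n_bursts
                flagged = bool(c.top10_size and c.top10_magnitude)
                break
    return {
        "detected": detected,
        "top10_flagged": flagged,
        "false_positive_clusters": len(control),
    }


def _validation_dataset(seed: int, n_individuals: int = 4, hours: float = 6.0,
                        fs: float = 8) -> pd.DataFrame:
    """GPS steps with percent-mobile from the generator's own labels."""
    frames = []
    rng = np.random.default_rng(seed)
    for i in range(n_individuals):
        sub = int(rng.integers(2**31))
        sched = Schedule.uniform_random(
            hours * 3600, seed=sub, labels=("rest", "low_move", "high_move"),
            mean_bout_s=300.0,
        )
        ds = synthetic.gen_dataset(sched, fs=fs, gps_interval=900.0, seed=sub)
        preds = ds.true_labels.rename(columns={"behavior": "label"}).copy()
        preds["label"] = classify.mobility_labels(preds["label"])
        steps = ethogram.step_distances(ds.gps)
        filled = ethogram.percent_mobile_per_interval(preds, steps)
        filled["individual_id"] = f"ind-{i:02d}"
        frames.append(filled)
    return pd.concat(frames, ignore_index=True)


def validation_replicate(seed: int, shuffle: bool = False, **kwargs) -> ethogram.MixedModelResult:
    """One mixed-model validation replicate.

    With ``shuffle=True`` the distance column is permuted first, breaking
    the mobility-distance link — the null used to calibrate the test's
    rejection rate.
    """
    steps = _validation_dataset(seed, **kwargs)
    if shuffle:
        rng = np.random.default_rng(seed + 10_000_019)
        steps = steps.assign(distance_m=rng.permutation(steps["distance_m"].to_numpy()))
    return ethogram.mobility_distance_model(steps)
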