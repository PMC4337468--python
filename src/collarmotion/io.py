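"""CSV dialects, configuration, duty-cycle masking and the pipeline driver.

All timestamps are ISO-8601 UTC. Accelerometer CSVs have columns
``timestamp, ax_g, ay_g, az_g`` (or raw counts with a counts-per-g scalar);
GPS CSVs have ``timestamp, lon, lat[, individual_id]``; label CSVs have
``window_start, behavior``. Calibration parameters serialise to a flat JSON
document (offset_x..scale_z).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import AccelTrace, CalibrationParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- CSV I/O


def write_accel_csv(trace: AccelTrace, path) -> None:
    df = trace.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df.to_csv(path, index=False, float_format="%.9f")


def read_accel_csv(path, counts_per_g: float | None = None) -> list[AccelTrace]:
    """Read an accelerometer CSV into uniformly sampled segments.

    Raw-count files are scaled by ``1/counts_per_g``. Gaps longer than twice
    the sampling period split the trace into separate segments. Malformed
    rows abort with their line number.
    """
    df = pd.read_csv(path)
    needed = ["timestamp", "ax_g", "ay_g", "az_g"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in needed:
        if col == "timestamp":
            parsed = pd.to_datetime(df[col], errors="coerce")
        else:
            parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad[0] + 2}")
        df[col] = parsed
    t = pd.DatetimeIndex(df["timestamp"])
    dt = np.diff(t.asi8) / 1e9
    if np.any(dt <= 0):
        raise ValueError(f"{path}: non-monotone timestamps at line {int(np.argmax(dt <= 0)) + 3}")
    data = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if counts_per_g is not None:
        data = data / counts_per_g
    if len(df) == 1:
        return [AccelTrace(data, fs=1.0, t0=t[0])]
    period = float(np.median(dt))
    fs = 1.0 / period
    breaks = np.nonzero(dt > 2 * period)[0]
    segments = []
    start = 0
    for b in list(breaks) + [len(df) - 1]:
        end = b + 1
        segments.append(AccelTrace(data[start:end], fs=fs, t0=t[start]))
        start = end
    return segments


def write_gps_csv(gps: pd.DataFrame, path) -> None:
    out = gps.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_gps_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if not {"timestamp", "lon", "lat"} <= set(df.columns):
        raise ValueError(f"{path}: GPS CSV needs timestamp, lon, lat")
    return df


def write_labels_csv(labels: pd.DataFrame, path) -> None:
    out = labels.rename(columns={"label": "behavior"}).copy()
    out["window_start"] = pd.DatetimeIndex(out["window_start"]).strftime(
        "%Y-%m-%dT%H:%M:%S.%f"
    )
    out.to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["window_start"])
    if not {"window_start", "behavior"} <= set(df.columns):
        raise ValueError(f"{path}: labels CSV needs window_start, behavior")
    return df


def write_calibration_json(params: CalibrationParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_calibration_json(path) -> CalibrationParams:
    try:
        return CalibrationParams.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"corrupt calibration file {path}: {exc}") from exc


def write_features_csv(features: pd.DataFrame, path) -> None:
    out = features.copy()
    out["window_start"] = pd.DatetimeIndex(out["window_start"]).strftime(
        "%Y-%m-%dT%H:%M:%S.%f"
    )
    out.to_csv(path, index=False, float_format="%.9f")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["window_start"])


# ------------------------------------------------------------ configuration


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serialisable to YAML."""

    fs: float = 64.0
    window_s: float = 2.0
    n_trees: int = 500
    subsample: int = 1000
    mtry: int = 5
    cluster_max_gap_s: float = 180.0
    cluster_min_size: int = 2
    threshold_override_g: float | None = 3.4
    gps_interval_s: float = 900.0
    gps_noise_sd_m: float = 10.0
    anesthesia_mask_h: float = 24.0
    timezone_offset_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fs", "window_s", "n_trees", "subsample", "mtry",
                     "cluster_max_gap_s", "cluster_min_size", "gps_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ------------------------------------------------------------- duty cycling


def apply_duty_cycle(
    trace: AccelTrace, on_s: float, off_s: float, start_offset_s: float = 0.0
) -> list[tuple[int, AccelTrace]]:
    """Retain samples in the on-phases of an on/off recording schedule.

    The schedule alternates ``on_s`` seconds recording with ``off_s``
    seconds off, starting at ``start_offset_s`` after the trace start.
    Returns (cycle index, segment) pairs; an empty result is an error.
    """
    if on_s <= 0 or off_s < 0:
        raise ValueError("on_s must be positive and off_s non-negative")
    period = on_s + off_s
    t = np.arange(len(trace)) / trace.fs - start_offset_s
    phase = np.mod(t, period)
    cycle = np.floor_divide(t, period).astype(int)
    keep = (phase < on_s) & (t >= 0)
    if not keep.any():
        raise ValueError("duty cycle retains no samples")
    segments = []
    for c in np.unique(cycle[keep]):
        mask = keep & (cycle == c)
        idx = np.nonzero(mask)[0]
        seg = AccelTrace(
            trace.data[idx],
            fs=trace.fs,
            t0=trace.t0 + pd.Timedelta(seconds=idx[0] / trace.fs),
        )
        segments.append((int(c), seg))
    return segments


def mask_initial_hours(trace: AccelTrace, hours: float) -> AccelTrace:
    """Drop the first ``hours`` of a trace (e.g. post-anesthesia recovery)."""
    n = int(round(hours * 3600 * trace.fs))
    if n >= len(trace):
        raise ValueError("mask removes the whole trace")
    return AccelTrace(
        trace.data[n:], fs=trace.fs, t0=trace.t0 + pd.Timedelta(hours=hours)
    )


# ---------------------------------------------------------------- pipeline


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Synthetic end-to-end run: simulate, calibrate, featurize, train,
    evaluate, budget, predation screen, GPS validation.

    Writes every stage artifact under ``outdir`` and returns their paths.
    Outputs embed the config hash and seed for provenance.
    """
    # imported here so io stays importable without the heavier deps at startup
    from . import calibration, classify, ethogram, predation, synthetic

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    provenance = {"config_hash": config.hash(), "seed": config.seed}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage name must propagate
                raise StageError(name, exc) from exc
        return wrap

    rng_seed = config.seed

    def _simulate():
        schedule = synthetic.Schedule.uniform_random(4 * 3600, seed=rng_seed)
        ds = synthetic.gen_dataset(
            schedule, fs=config.fs, gps_interval=config.gps_interval_s,
            seed=rng_seed, gps_noise_sd=config.gps_noise_sd_m,
        )
        truth = CalibrationParams(offset=[0.08, -0.12, 0.05], scale=[1.06, 0.94, 1.03])
        raw = synthetic.inject_miscalibration(ds.trace, truth)
        raw, events = synthetic.inject_predation(
            raw, at=2 * 3600, n_bursts=5, burst_magnitude=4.5, gap=60.0, seed=rng_seed
        )
        tumble = synthetic.gen_tumble(truth, 500, noise_sd=0.005, seed=rng_seed)
        write_accel_csv(raw, outdir / "accel_raw.csv")
        write_gps_csv(ds.gps, outdir / "gps.csv")
        write_labels_csv(ds.true_labels.rename(columns={"behavior": "label"}),
                         outdir / "labels.csv")
        np.savetxt(outdir / "tumble.csv", tumble, delimiter=",", header="x,y,z", comments="")
        paths.update({k: outdir / f"{k}.csv" for k in ("accel_raw", "gps", "labels", "tumble")})
        return raw, ds, events, tumble

    raw, ds, events, tumble = stage("simulate")(_simulate)

    def _calibrate():
        params = calibration.fit_calibration(tumble)
        write_calibration_json(params, outdir / "calibration.json")
        paths["calibration"] = outdir / "calibration.json"
        return calibration.apply_calibration(raw, params)

    cal = stage("calibrate")(_calibrate)

    def _featurize():
        from .features import features_frame
        feats = features_frame(cal, labels=ds.true_labels["behavior"].to_numpy())
        write_features_csv(feats, outdir / "features.csv")
        paths["features"] = outdir / "features.csv"
        return feats

    feats = stage("featurize")(_featurize)

    def _train_eval():
        y = classify.mobility_labels(feats["label"])
        tr, te = classify.train_test_split_indices(y, 0.3, seed=rng_seed)
        model = classify.train(
            feats.iloc[tr], y[tr], task="mobility", seed=rng_seed,
            n_trees=config.n_trees, subsample=config.subsample, mtry=config.mtry,
        )
        cm = classify.evaluate(model, feats.iloc[te], y[te])
        out = cm.to_frame()
        out.attrs.update(provenance)
        out.to_csv(outdir / "confusion_mobility.csv")
        paths["confusion_mobility"] = outdir / "confusion_mobility.csv"
        preds = pd.DataFrame(
            {"window_start": feats["window_start"], "label": model.predict(feats)}
        )
        preds.to_csv(outdir / "predictions.csv", index=False)
        paths["predictions"] = outdir / "predictions.csv"
        return preds

    preds = stage("train")(_train_eval)

    def _budget():
        budget = ethogram.hourly_budget(preds)
        budget.to_csv(outdir / "budget.csv", index=False)
        paths["budget"] = outdir / "budget.csv"

    stage("budget")(_budget)

    def _predation():
        thr = predation.high_acc_threshold(
            feats["mag_range"].to_numpy(), override=config.threshold_override_g
        )
        clusters = predation.find_clusters(
            feats["window_start"], feats["mag_range"].to_numpy() > thr,
            feats["mag_range"].to_numpy(),
            max_gap=config.cluster_max_gap_s, min_size=config.cluster_min_size,
        )
        if clusters:
            predation.rank_clusters(clusters)
            predation.clusters_frame(clusters).to_csv(outdir / "clusters.csv", index=False)
        else:
            pd.DataFrame().to_csv(outdir / "clusters.csv", index=False)
        paths["clusters"] = outdir / "clusters.csv"

    stage("predation")(_predation)

    def _validate():
        gps = ds.gps.copy()
        gps["individual_id"] = "synthetic-01"
        steps = ethogram.step_distances(gps)
        filled = ethogram.percent_mobile_per_interval(preds, steps)
        summary = {
            "n_steps": len(filled),
            "corr_distance_percent_mobile": float(
                filled["distance_m"].corr(filled["percent_mobile"], method="spearman")
            ),
            **provenance,
        }
        (outdir / "validation.json").write_text(json.dumps(summary, indent=2) + "\n")
        paths["validation"] = outdir / "validation.json"

    stage("validate")(_validate)

    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    paths["provenance"] = outdir / "provenance.json"
    return paths
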