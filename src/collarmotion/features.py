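"""Windowing and predictor extraction for 2-s accelerometer segments.

Each calibrated trace is cut into consecutive non-overlapping 2-s windows.
Within a window the static (gravity/posture) component is the per-axis mean
and the dynamic component is the residual. From the dynamic signal and its
magnitude the 16 classifier predictors are computed:

* ODBA_X/Y/Z — mean absolute dynamic acceleration per axis (g), and their
  sum ODBA (overall dynamic body acceleration);
* Amp_X/Y/Z/M and DF_X/Y/Z/M — amplitude (g) and frequency (Hz) of the
  dominant FFT bin, DC excluded, per dynamic axis and for the mean-subtracted
  dynamic magnitude;
* SD_X/Y/Z/M — standard deviation (g) of each dynamic axis and of the
  magnitude.

The within-window range of the *calibrated* (pre-subtraction) magnitude,
``mag_range``, is carried along as an auxiliary column for predation
screening; it is not a model predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .trace import AccelTrace

WINDOW_S = 2.0

#: the 16 model predictors, in canonical column order
FEATURE_COLUMNS = [
    "ODBA_X", "ODBA_Y", "ODBA_Z", "ODBA",
    "Amp_X", "Amp_Y", "Amp_Z", "Amp_M",
    "DF_X", "DF_Y", "DF_Z", "DF_M",
    "SD_X", "SD_Y", "SD_Z", "SD_M",
]


@dataclass
class Window:
    """One 2-s segment of a calibrated trace."""

    start: pd.Timestamp
    fs: float
    samples: np.ndarray  # (n, 3), n = window_s * fs
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite samples")


def segment(trace: AccelTrace, window_s: float = WINDOW_S) -> list[Window]:
    """Cut a trace into consecutive non-overlapping windows.

    A trailing partial window is dropped; an input shorter than one window
    yields an empty list with a warning.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    n = int(round(window_s * trace.fs))
    count = len(trace) // n
    if count == 0:
        warnings.warn("trace shorter than one window: no windows produced", stacklevel=2)
        return []
    step = pd.Timedelta(seconds=window_s)
    return [
        Window(start=trace.t0 + k * step, fs=trace.fs, samples=trace.data[k * n : (k + 1) * n])
        for k in range(count)
    ]


def split_static_dynamic(window: Window | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Separate posture (gravity) from movement within one window.

    static = per-axis mean; dynamic = samples - static (zero mean per axis).
    """
    samples = window.samples if isinstance(window, Window) else np.asarray(window, float)
    static = samples.mean(axis=0)
    return static, samples - static


def magnitude(samples: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm across the three axes."""
    return np.linalg.norm(np.asarray(samples, dtype=float), axis=-1)


def odba(dynamic: np.ndarray) -> tuple[np.ndarray, float]:
    """Dynamic body acceleration: per-axis mean |dynamic| and their sum."""
    per_axis = np.mean(np.abs(dynamic), axis=0)
    return per_axis, float(per_axis.sum())


def dominant_spectrum(sig: np.ndarray, fs: float) -> tuple[float, float]:
    """Dominant frequency (Hz) and its amplitude (g) of a mean-removed signal.

    The DC bin is excluded; the amplitude is normalised as ``2|X_k|/n`` so a
    unit sinusoid at a bin frequency reports amplitude 1. Ties go to the
    lower frequency, so an all-zero signal reports the first non-DC bin
    (0.5 Hz for 2-s windows) with amplitude 0.
    """
    sig = np.asarray(sig, dtype=float)
    n = sig.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a spectrum")
    amps = 2.0 * np.abs(np.fft.rfft(sig)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    k = 1 + int(np.argmax(amps[1:]))  # argmax takes the first (lowest) max
    return float(freqs[k]), float(amps[k])


def _window_stack(trace: AccelTrace, window_s: float = WINDOW_S) -> tuple[np.ndarray, pd.DatetimeIndex]:
    n = int(round(window_s * trace.fs))
    count = len(trace) // n
    stack = trace.data[: count * n].reshape(count, n, 3)
    starts = trace.t0 + pd.to_timedelta(np.arange(count) * window_s, unit="s")
    return stack, starts


def _features_from_stack(stack: np.ndarray, fs: float) -> pd.DataFrame:
    """Vectorised predictor computation over a (nwin, n, 3) window stack."""
    n = stack.shape[1]
    dyn = stack - stack.mean(axis=1, keepdims=True)
    odba_axes = np.abs(dyn).mean(axis=1)  # (nwin, 3)
    odba_tot = odba_axes.sum(axis=1)

    mag = np.linalg.norm(stack, axis=2)  # calibrated magnitude, (nwin, n)
    mag_range = mag.max(axis=1) - mag.min(axis=1)

    dyn_mag = np.linalg.norm(dyn, axis=2)
    dyn_mag_c = dyn_mag - dyn_mag.mean(axis=1, keepdims=True)

    sd_axes = dyn.std(axis=1)  # (nwin, 3)
    sd_m = dyn_mag.std(axis=1)

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sig4 = np.concatenate([dyn, dyn_mag_c[:, :, None]], axis=2)  # (nwin, n, 4)
    amps = 2.0 * np.abs(np.fft.rfft(sig4, axis=1)) / n
    k = 1 + np.argmax(amps[:, 1:, :], axis=1)  # first max = lowest frequency
    df = freqs[k]  # (nwin, 4)
    amp = np.take_along_axis(amps, k[:, None, :], axis=1)[:, 0, :]

    out = {
        "ODBA_X": odba_axes[:, 0], "ODBA_Y": odba_axes[:, 1], "ODBA_Z": odba_axes[:, 2],
        "ODBA": odba_tot,
        "Amp_X": amp[:, 0], "Amp_Y": amp[:, 1], "Amp_Z": amp[:, 2], "Amp_M": amp[:, 3],
        "DF_X": df[:, 0], "DF_Y": df[:, 1], "DF_Z": df[:, 2], "DF_M": df[:, 3],
        "SD_X": sd_axes[:, 0], "SD_Y": sd_axes[:, 1], "SD_Z": sd_axes[:, 2], "SD_M": sd_m,
        "mag_range": mag_range,
    }
    return pd.DataFrame(out)


def extract_features(window: Window) -> pd.Series:
    """The 16 predictors plus ``mag_range`` for a single window."""
    row = _features_from_stack(window.samples[None, :, :], window.fs).iloc[0]
    row.name = window.start
    return row


def features_frame(
    trace: AccelTrace,
    labels: np.ndarray | pd.Series | None = None,
    window_s: float = WINDOW_S,
) -> pd.DataFrame:
    """Feature table for a whole trace: one row per window.

    Columns: ``window_start``, the 16 predictors, ``mag_range`` and, when
    per-window labels are supplied, ``label``.
    """
    stack, starts = _window_stack(trace, window_s)
    if stack.shape[0] == 0:
        raise ValueError("trace shorter than one window")
    df = _features_from_stack(stack, trace.fs)
    df.insert(0, "window_start", starts)
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] < df.shape[0]:
            raise ValueError("fewer labels than windows")
        df["label"] = labels[: df.shape[0]]
    return df


def downsample(trace: AccelTrace, target_fs: float, antialias: bool = False) -> AccelTrace:
    """Decimate a trace to a lower sampling frequency.

    Default is plain decimation (every ``fs/target_fs``-th sample, no
    filtering), which mimics what a sensor simply sampling slower would
    record for band-limited motion; ``antialias=True`` applies a low-pass
    filter (scipy's decimate) first.
    """
    ratio = trace.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or target_fs <= 0:
        raise ValueError(f"target_fs {target_fs} must divide fs {trace.fs}")
    q = int(round(ratio))
    if q == 1:
        return AccelTrace(trace.data.copy(), fs=trace.fs, t0=trace.t0)
    if antialias:
        data = _sig.decimate(trace.data, q, axis=0, zero_phase=True)
    else:
        data = trace.data[::q]
    return AccelTrace(np.ascontiguousarray(data), fs=target_fs, t0=trace.t0)
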