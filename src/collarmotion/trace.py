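"""Core containers for collar accelerometer data.

Axis convention follows the usual collar mounting: x is surge
(anterior-posterior), y is sway (transverse), z is heave (dorsal-ventral).
Calibrated values are in units of g (1 g = 9.8 m s^-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AXES = ("x", "y", "z")


@dataclass
class AccelTrace:
    """A uniformly sampled tri-axial acceleration series.

    Parameters
    ----------
    data:
        ``(n, 3)`` float array, columns x/y/z. Units are g for calibrated
        traces and raw sensor units for uncalibrated ones.
    fs:
        Sampling frequency in Hz.
    t0:
        Timestamp of the first sample (UTC).
    """

    data: np.ndarray
    fs: float
    t0: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2020-01-01"))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must be an (n, 3) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.t0 = pd.Timestamp(self.t0)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self) / self.fs

    def times(self) -> pd.DatetimeIndex:
        """Per-sample timestamps."""
        step = pd.Timedelta(seconds=1.0 / self.fs)
        return self.t0 + step * np.arange(len(self))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=[f"a{ax}_g" for ax in AXES])
        df.insert(0, "timestamp", self.times())
        return df


@dataclass
class CalibrationParams:
    """Per-axis accelerometer error model: ``raw = scale * true + offset``.

    ``offset`` is the null shift in g; ``scale`` is the dimensionless scale
    factor. A perfectly calibrated sensor has offset (0, 0, 0) and scale
    (1, 1, 1), so tumble samples lie on the unit-g sphere.
    """

    offset: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        self.scale = np.asarray(self.scale, dtype=float).reshape(3)
        if np.any(self.scale <= 0):
            raise ValueError("scale factors must be positive")

    @classmethod
    def identity(cls) -> "CalibrationParams":
        return cls(offset=np.zeros(3), scale=np.ones(3))

    def to_dict(self) -> dict:
        keys = [f"offset_{ax}" for ax in AXES] + [f"scale_{ax}" for ax in AXES]
        vals = list(self.offset) + list(self.scale)
        return {k: float(v) for k, v in zip(keys, vals)}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationParams":
        return cls(
            offset=[d[f"offset_{ax}"] for ax in AXES],
            scale=[d[f"scale_{ax}"] for ax in AXES],
        )
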