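"""Screening accelerometer records for predation events.

Attacks on large prey show up as clusters of violent movements: windows
whose within-window magnitude range exceeds a high-acceleration threshold
(mean + 2 SD of the individual's per-window magnitude ranges, ~3.4 g for the
original collars; a fixed override is accepted). A cluster is two or more
flagged windows with successive gaps of at most three minutes. Clusters are
ranked by size (flagged-window count) and by maximum magnitude range, and a
cluster supports a candidate kill when it intersects the window from one GPS
sampling interval before the feeding event's start through the end of the
event's first quartile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_THRESHOLD_G = 3.4
MAX_GAP_S = 180.0
MIN_CLUSTER_SIZE = 2


def high_acc_threshold(
    mag_ranges: np.ndarray,
    override: float | None = None,
    min_windows: int = 100,
) -> float:
    """High-acceleration threshold for one individual.

    mean + 2 SD of the per-window magnitude ranges, or the fixed
    ``override`` (e.g. the canonical 3.4 g) when given.
    """
    if override is not None:
        return float(override)
    x = np.asarray(mag_ranges, dtype=float)
    if x.size < min_windows:
        raise ValueError(f"need at least {min_windows} windows to set a threshold")
    return float(x.mean() + 2.0 * x.std())


@dataclass
class ClusterRecord:
    """A detected cluster of high-acceleration windows."""

    start: pd.Timestamp
    end: pd.Timestamp
    size: int
    duration_s: float
    max_mag_range: float
    size_percentile: float | None = None
    magnitude_percentile: float | None = None
    top10_size: bool | None = None
    top10_magnitude: bool | None = None


def find_clusters(
    timestamps,
    flags,
    mag_ranges=None,
    max_gap: float = MAX_GAP_S,
    min_size: int = MIN_CLUSTER_SIZE,
    window_s: float = 2.0,
) -> list[ClusterRecord]:
    """Group flagged windows into clusters.

    A cluster is a maximal run of flagged windows whose successive flagged
    timestamps differ by at most ``max_gap`` seconds; runs smaller than
    ``min_size`` are discarded. ``timestamps`` are window starts (datetime
    or seconds); ``mag_ranges`` supplies the per-window magnitude ranges for
    the cluster maxima (flagged windows only may also be given implicitly).
    """
    flags = np.asarray(flags, dtype=bool)
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps)) if not np.issubdtype(
        np.asarray(timestamps).dtype, np.number
    ) else None
    if ts is not None:
        t_sec = ts.asi8 / 1e9
    else:
        t_sec = np.asarray(timestamps, dtype=float)
    if t_sec.shape[0] != flags.shape[0]:
        raise ValueError("flags/timestamps length mismatch")
    if np.any(np.diff(t_sec) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if mag_ranges is not None:
        mag_ranges = np.asarray(mag_ranges, dtype=float)
        if mag_ranges.shape[0] != flags.shape[0]:
            raise ValueError("mag_ranges length mismatch")

    idx = np.nonzero(flags)[0]
    clusters: list[ClusterRecord] = []
    if idx.size == 0:
        return clusters
    breaks = np.nonzero(np.diff(t_sec[idx]) > max_gap)[0]
    groups = np.split(idx, breaks + 1)
    for grp in groups:
        if grp.size < min_size:
            continue
        start_s, end_s = t_sec[grp[0]], t_sec[grp[-1]] + window_s
        if ts is not None:
            start = ts[grp[0]]
            end = ts[grp[-1]] + pd.Timedelta(seconds=window_s)
        else:
            start = pd.Timestamp(start_s, unit="s")
            end = pd.Timestamp(end_s, unit="s")
        clusters.append(
            ClusterRecord(
                start=start,
                end=end,
                size=int(grp.size),
                duration_s=float(end_s - start_s),
                max_mag_range=float(mag_ranges[grp].max()) if mag_ranges is not None else np.nan,
            )
        )
    return clusters


def rank_clusters(clusters: list[ClusterRecord]) -> list[ClusterRecord]:
    """Attach size and magnitude percentiles and top-10% flags (in place).

    Percentile = 100 * rank / N with the largest value at the 100th
    percentile; ties share the higher percentile. The top-10% flag requires
    a percentile strictly above 90, so exactly one of ten distinct values is
    flagged while a full tie flags everything.
    """
    if not clusters:
        raise ValueError("no clusters to rank")
    n = len(clusters)
    sizes = np.array([c.size for c in clusters], dtype=float)
    mags = np.array([c.max_mag_range for c in clusters], dtype=float)
    size_pct = 100.0 * rankdata(sizes, method="max") / n
    mag_pct = 100.0 * rankdata(mags, method="max") / n
    for c, sp, mp in zip(clusters, size_pct, mag_pct):
        c.size_percentile = float(sp)
        c.magnitude_percentile = float(mp)
        c.top10_size = bool(sp > 90.0)
        c.top10_magnitude = bool(mp > 90.0)
    return clusters


def clusters_frame(clusters: list[ClusterRecord]) -> pd.DataFrame:
    """Clusters as a table (one row each)."""
    return pd.DataFrame([vars(c) for c in clusters])


@dataclass
class FeedingEvent:
    """A GPS-derived kill-site interval.

    The event spans from 4 h before the first fix at the site (a kill may
    have happened during the preceding GPS gap) to the last fix there.
    """

    first_fix: pd.Timestamp
    last_fix: pd.Timestamp
    pre_interval: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(hours=4))

    def __post_init__(self) -> None:
        self.first_fix = pd.Timestamp(self.first_fix)
        self.last_fix = pd.Timestamp(self.last_fix)
        if self.first_fix > self.last_fix:
            raise ValueError("first_fix must not be after last_fix")

    @property
    def event_start(self) -> pd.Timestamp:
        return self.first_fix - self.pre_interval

    @property
    def event_end(self) -> pd.Timestamp:
        return self.last_fix

    @property
    def first_quartile_end(self) -> pd.Timestamp:
        return self.event_start + 0.25 * (self.event_end - self.event_start)


def event_overlap(
    cluster: ClusterRecord, event: FeedingEvent, gps_interval: float = 900.0
) -> bool:
    """Does a cluster fall in the event's kill-plausible span?

    True iff the cluster intersects [event_start - gps_interval,
    first_quartile_end], i.e. from one GPS sampling interval before the
    event start through the end of its first quartile.
    """
    if event.event_start >= event.event_end:
        raise ValueError("degenerate feeding event")
    lo = event.event_start - pd.Timedelta(seconds=gps_interval)
    hi = event.first_quartile_end
    return bool(cluster.end >= lo and cluster.start <= hi)
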