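"""Activity budgets and GPS-based validation of predicted mobility.

Model predictions (one mobility class per 2-s window) are summarised as
24-hour activity budgets — the proportion of windows classified mobile in
each clock hour, pooled across days — and validated against independent GPS
data: over each inter-fix interval the percentage of time predicted mobile
should scale with the straight-line distance between the fixes. The
validation model is a linear mixed model, distance ~ percent_mobile with a
per-individual random intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .classify import MOBILE

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8  # WGS84 mean radius
WINDOW_S = 2.0


def hourly_budget(preds: pd.DataFrame, mobile_label: str = MOBILE) -> pd.DataFrame:
    """24-hour activity budget from a prediction series.

    ``preds`` needs columns ``window_start`` (datetime) and ``label``. For
    each clock hour the mobile proportion is pooled across days; the
    across-day SD of the daily proportions is reported alongside. Hours with
    no data keep NaN proportions and are flagged, not zero-filled.
    """
    if preds.empty:
        raise ValueError("empty prediction series")
    t = pd.DatetimeIndex(preds["window_start"])
    mobile = (preds["label"].to_numpy() == mobile_label).astype(float)
    df = pd.DataFrame({"hour": t.hour, "day": t.normalize(), "mobile": mobile})
    pooled = df.groupby("hour")["mobile"].agg(["mean", "size"])
    daily = df.groupby(["hour", "day"])["mobile"].mean().groupby("hour").std()
    out = pd.DataFrame({"hour": np.arange(24)})
    out["proportion_mobile"] = out["hour"].map(pooled["mean"])
    out["n_windows"] = out["hour"].map(pooled["size"]).fillna(0).astype(int)
    out["sd_across_days"] = out["hour"].map(daily)
    out["has_data"] = out["n_windows"] > 0
    return out


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres between WGS84 degree coordinates."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def step_distances(fixes: pd.DataFrame, coords: str = "lonlat") -> pd.DataFrame:
    """Distances between successive GPS fixes.

    ``fixes`` needs ``timestamp`` plus ``lon``/``lat`` (``coords="lonlat"``)
    or planar ``x_m``/``y_m`` (``coords="planar"``, for synthetic tracks).
    Returns one row per step: t_start, t_end, interval_s, distance_m.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes")
    t = pd.DatetimeIndex(fixes["timestamp"])
    dt = np.diff(t.asi8) / 1e9
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if coords == "lonlat":
        lon, lat = fixes["lon"].to_numpy(), fixes["lat"].to_numpy()
        dist = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
    elif coords == "planar":
        x, y = fixes["x_m"].to_numpy(), fixes["y_m"].to_numpy()
        dist = np.hypot(np.diff(x), np.diff(y))
    else:
        raise ValueError("coords must be 'lonlat' or 'planar'")
    out = pd.DataFrame(
        {"t_start": t[:-1], "t_end": t[1:], "interval_s": dt, "distance_m": dist}
    )
    if "individual_id" in fixes.columns:
        out["individual_id"] = fixes["individual_id"].to_numpy()[:-1]
    return out


def percent_mobile_per_interval(
    preds: pd.DataFrame,
    steps: pd.DataFrame,
    mobile_label: str = MOBILE,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Fill each GPS step with the percent of its windows predicted mobile.

    Steps whose prediction coverage (windows present / windows expected at
    one per 2 s) falls below ``min_coverage`` are dropped and logged.
    """
    t = pd.DatetimeIndex(preds["window_start"])
    mobile = preds["label"].to_numpy() == mobile_label
    order = np.argsort(t.asi8)
    tt = t.asi8[order] / 1e9
    mm = mobile[order]
    cum_mobile = np.concatenate([[0], np.cumsum(mm)])

    rows = []
    for _, step in steps.iterrows():
        lo = pd.Timestamp(step["t_start"]).value / 1e9
        hi = pd.Timestamp(step["t_end"]).value / 1e9
        i0, i1 = np.searchsorted(tt, [lo, hi])
        n = i1 - i0
        expected = (hi - lo) / WINDOW_S
        if expected <= 0 or n / expected < min_coverage:
            logger.info(
                "dropping interval %s..%s: coverage %.0f%% < %.0f%%",
                step["t_start"], step["t_end"], 100 * n / max(expected, 1),
                100 * min_coverage,
            )
            continue
        rec = dict(step)
        rec["n_windows"] = int(n)
        rec["percent_mobile"] = 100.0 * (cum_mobile[i1] - cum_mobile[i0]) / n
        rows.append(rec)
    if not rows:
        raise ValueError("no step overlaps the prediction series")
    return pd.DataFrame(rows)


@dataclass
class MixedModelResult:
    """Fixed-effect slope of distance on percent mobile, with diagnostics."""

    slope: float
    se: float
    pvalue: float
    intercept: float
    random_intercept_var: float
    n_steps: int
    n_individuals: int
    converged: bool
    singular: bool


def mobility_distance_model(steps: pd.DataFrame, min_steps: int = 30) -> MixedModelResult:
    """Linear mixed model: step distance ~ percent mobile + (1 | individual).

    Requires ``distance_m``, ``percent_mobile`` and ``individual_id``
    columns, at least two individuals and ``min_steps`` steps. A singular
    fit (random-intercept variance on the boundary) is reported in the
    result, never silently dropped.
    """
    needed = {"distance_m", "percent_mobile", "individual_id"}
    if not needed <= set(steps.columns):
        raise ValueError(f"steps table needs columns {sorted(needed)}")
    if steps["individual_id"].nunique() < 2:
        raise ValueError("need at least 2 individuals for a random intercept")
    if len(steps) < min_steps:
        raise ValueError(f"need at least {min_steps} steps")
    if np.isclose(steps["percent_mobile"].std(), 0.0):
        raise ValueError("percent_mobile has no variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "distance_m ~ percent_mobile", data=steps, groups=steps["individual_id"]
        )
        fit = model.fit(reml=True, method="lbfgs")
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    singular = re_var < 1e-8 * max(float(fit.scale), 1.0)
    if singular:
        logger.warning("singular mixed-model fit: random-intercept variance ~ 0")
    return MixedModelResult(
        slope=float(fit.params["percent_mobile"]),
        se=float(fit.bse["percent_mobile"]),
        pvalue=float(fit.pvalues["percent_mobile"]),
        intercept=float(fit.params["Intercept"]),
        random_intercept_var=re_var,
        n_steps=len(steps),
        n_individuals=int(steps["individual_id"].nunique()),
        converged=bool(fit.converged),
        singular=singular,
    )


def nocturnality_summary(budget_by_individual: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Convenience table: mean hourly mobility, day vs night, per individual.

    Night is 18:00-06:00. Provided as a descriptive summary only.
    """
    rows = []
    for ind, budget in budget_by_individual.items():
        b = budget[budget["has_data"]]
        night = b[(b["hour"] >= 18) | (b["hour"] < 6)]["proportion_mobile"].mean()
        day = b[(b["hour"] >= 6) & (b["hour"] < 18)]["proportion_mobile"].mean()
        rows.append(
            {"individual_id": ind, "night_mean": night, "day_mean": day,
             "nocturnality_ratio": night / day if day and day > 0 else np.inf}
        )
    return pd.DataFrame(rows)
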