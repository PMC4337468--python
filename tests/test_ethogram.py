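"""Activity budgets, GPS step geometry and the mixed-model validation."""

import numpy as np
import pandas as pd
import pytest

from collarmotion import ethogram, experiments
from collarmotion.classify import MOBILE, NON_MOBILE


def pred_series(labels, start="2020-01-01", step_s=2.0):
    t = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(labels)) * step_s, unit="s")
    return pd.DataFrame({"window_start": t, "label": labels})


class TestHourlyBudget:
    def test_all_rest_day(self):
        preds = pred_series([NON_MOBILE] * (24 * 1800))
        budget = ethogram.hourly_budget(preds)
        assert (budget["proportion_mobile"] == 0).all()
        assert budget["has_data"].all()

    def test_nocturnal_schedule(self):
        hours = pd.date_range("2020-01-01", periods=24 * 1800, freq="2s").hour
        labels = np.where((hours >= 18) | (hours < 6), MOBILE, NON_MOBILE)
        budget = ethogram.hourly_budget(pred_series(labels))
        night = (budget["hour"] >= 18) | (budget["hour"] < 6)
        assert (budget.loc[night, "proportion_mobile"] == 1).all()
        assert (budget.loc[~night, "proportion_mobile"] == 0).all()

    def test_alternating_windows_near_half(self):
        labels = np.where(np.arange(4 * 1800) % 2 == 0, MOBILE, NON_MOBILE)
        budget = ethogram.hourly_budget(pred_series(labels))
        got = budget[budget["has_data"]]["proportion_mobile"]
        assert np.allclose(got, 0.5, atol=1 / np.sqrt(1800))

    def test_budget_conservation(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([MOBILE, NON_MOBILE], size=5000)
        budget = ethogram.hourly_budget(pred_series(labels))
        total = np.nansum(budget["proportion_mobile"] * budget["n_windows"])
        assert total == pytest.approx(np.sum(labels == MOBILE))

    def test_missing_hours_flagged_not_zeroed(self):
        budget = ethogram.hourly_budget(pred_series([MOBILE] * 1800))  # 1 hour only
        assert budget["has_data"].sum() == 1
        assert budget.loc[~budget["has_data"], "proportion_mobile"].isna().all()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ethogram.hourly_budget(pd.DataFrame(columns=["window_start", "label"]))


class TestStepDistances:
    def test_identical_positions_zero(self):
        fixes = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2020-01-01 00:00", "2020-01-01 00:15"]),
             "lon": [-122.0, -122.0], "lat": [37.0, 37.0]}
        )
        assert ethogram.step_distances(fixes)["distance_m"][0] == 0.0

    def test_milli_degree_latitude_closed_form(self):
        fixes = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2020-01-01 00:00", "2020-01-01 00:15"]),
             "lon": [0.0, 0.0], "lat": [0.0, 0.001]}
        )
        d = ethogram.step_distances(fixes)["distance_m"][0]
        assert d == pytest.approx(111.195, abs=0.01)

    def test_unordered_timestamps_rejected(self):
        fixes = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2020-01-02 00:00", "2020-01-01 00:00"]),
             "lon": [0.0, 0.0], "lat": [0.0, 0.1]}
        )
        with pytest.raises(ValueError):
            ethogram.step_distances(fixes)

    def test_planar_mode_matches_hypot(self):
        fixes = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2020-01-01 00:00", "2020-01-01 00:15"]),
             "x_m": [0.0, 30.0], "y_m": [0.0, 40.0]}
        )
        d = ethogram.step_distances(fixes, coords="planar")["distance_m"][0]
        assert d == pytest.approx(50.0)


class TestPercentMobile:
    def make_steps(self, n=2, interval_s=900):
        t = pd.Timestamp("2020-01-01") + pd.to_timedelta(
            np.arange(n + 1) * interval_s, unit="s"
        )
        return pd.DataFrame(
            {"t_start": t[:-1], "t_end": t[1:],
             "interval_s": interval_s, "distance_m": 0.0}
        )

    def test_fully_rest_interval_zero_percent(self):
        preds = pred_series([NON_MOBILE] * 900)
        out = ethogram.percent_mobile_per_interval(preds, self.make_steps())
        assert (out["percent_mobile"] == 0).all()

    def test_half_mobile_interval(self):
        labels = ([MOBILE] * 225 + [NON_MOBILE] * 225) * 2
        out = ethogram.percent_mobile_per_interval(pred_series(labels), self.make_steps())
        assert out["percent_mobile"].iloc[0] == pytest.approx(50.0)
        assert out["n_windows"].iloc[0] == 450

    def test_low_coverage_interval_dropped(self):
        # predictions cover only 70% of the second interval
        labels = [MOBILE] * (450 + 315)
        out = ethogram.percent_mobile_per_interval(pred_series(labels), self.make_steps())
        assert len(out) == 1

    def test_no_overlap_rejected(self):
        preds = pred_series([MOBILE] * 10, start="2021-06-01")
        with pytest.raises(ValueError):
            ethogram.percent_mobile_per_interval(preds, self.make_steps())


class TestMobilityDistanceModel:
    def test_generator_link_gives_positive_significant_slope(self):
        result = experiments.validation_replicate(seed=42)
        assert result.slope > 0
        assert result.pvalue < 1e-3
        assert result.n_individuals >= 2

    def test_constant_predictor_rejected(self):
        steps = pd.DataFrame(
            {"distance_m": np.random.default_rng(0).normal(100, 10, 40),
             "percent_mobile": 50.0,
             "individual_id": ["a", "b"] * 20}
        )
        with pytest.raises(ValueError, match="variance"):
            ethogram.mobility_distance_model(steps)

    def test_too_few_individuals_rejected(self):
        steps = pd.DataFrame(
            {"distance_m": np.arange(40.0), "percent_mobile": np.arange(40.0),
             "individual_id": "a"}
        )
        with pytest.raises(ValueError, match="individuals"):
            ethogram.mobility_distance_model(steps)

    def test_rank_correlation_with_commanded_speed(self):
        # generator property: per-interval percent mobile tracks the
        # commanded mean speed (single mobile class: the link is monotone)
        from collarmotion import synthetic as syn
        from collarmotion.classify import mobility_labels

        sched = syn.Schedule.uniform_random(
            4 * 3600, seed=7, labels=("rest", "low_move"), mean_bout_s=300.0
        )
        ds = syn.gen_dataset(sched, fs=2, gps_interval=900.0, seed=7)
        preds = ds.true_labels.rename(columns={"behavior": "label"}).copy()
        speeds = preds["label"].map(lambda b: syn.DEFAULT_BEHAVIORS[b].speed).to_numpy()
        preds["label"] = mobility_labels(preds["label"])
        steps = ethogram.step_distances(ds.gps)
        filled = ethogram.percent_mobile_per_interval(preds, steps)
        # commanded mean speed per interval from the schedule itself
        per_interval_speed = [
            speeds[i * 450:(i + 1) * 450].mean() for i in range(len(filled))
        ]
        rho = pd.Series(per_interval_speed).corr(
            filled["percent_mobile"].reset_index(drop=True), method="spearman"
        )
        assert rho >= 0.8
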