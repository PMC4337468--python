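"""Windowing, static/dynamic split, spectral predictors and decimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collarmotion import synthetic as syn
from collarmotion.features import (
    FEATURE_COLUMNS,
    Window,
    dominant_spectrum,
    downsample,
    extract_features,
    features_frame,
    magnitude,
    odba,
    segment,
    split_static_dynamic,
)
from collarmotion.trace import AccelTrace


def sine_window(freq=3.0, amp=1.0, fs=64, axis=2, offset=(0.0, 0.0, 0.0)):
    t = np.arange(int(2 * fs)) / fs
    data = np.tile(np.asarray(offset, float), (t.size, 1))
    data[:, axis] += amp * np.sin(2 * np.pi * freq * t)
    return Window(start=pd.Timestamp("2020-01-01"), fs=fs, samples=data)


class TestSegment:
    @pytest.mark.parametrize(
        "duration,expected", [(10.0, 5), (9.5, 4)]
    )
    def test_window_counts(self, duration, expected):
        trace = AccelTrace(np.zeros((int(duration * 64), 3)), fs=64)
        wins = segment(trace)
        assert len(wins) == expected
        assert all(w.samples.shape == (128, 3) for w in wins)

    def test_short_trace_warns(self):
        trace = AccelTrace(np.zeros((64, 3)), fs=64)
        with pytest.warns(UserWarning):
            assert segment(trace) == []

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            segment(AccelTrace(np.zeros((0, 3)), fs=64))


class TestStaticDynamic:
    def test_constant_window(self):
        w = sine_window(amp=0.0, offset=(0, 0, 1))
        static, dyn = split_static_dynamic(w)
        assert static == pytest.approx([0, 0, 1])
        assert np.allclose(dyn, 0)

    def test_zero_mean_sinusoid_passthrough(self):
        w = sine_window(freq=3, amp=0.8)
        static, dyn = split_static_dynamic(w)
        assert abs(static[2]) < 1e-12  # whole cycles average to zero
        assert np.allclose(dyn, w.samples)

    def test_offset_invariance_of_dynamic(self):
        base = sine_window(freq=3, amp=0.8)
        shifted = sine_window(freq=3, amp=0.8, offset=(0, 0, 0.3))
        _, dyn_a = split_static_dynamic(base)
        _, dyn_b = split_static_dynamic(shifted)
        assert np.allclose(dyn_a, dyn_b, atol=1e-12)


class TestMagnitudeOdba:
    def test_three_four_five(self):
        assert magnitude(np.array([[0.6, 0.8, 0.0]]))[0] == pytest.approx(1.0)

    def test_unit_diagonal(self):
        assert magnitude(np.array([[1.0, 1.0, 1.0]]))[0] == pytest.approx(np.sqrt(3))

    def test_odba_square_wave(self):
        dyn = np.zeros((128, 3))
        dyn[::2, 2], dyn[1::2, 2] = 0.5, -0.5
        per_axis, total = odba(dyn)
        assert per_axis == pytest.approx([0, 0, 0.5])
        assert total == pytest.approx(0.5)

    def test_odba_sinusoid_closed_form(self):
        # mean |A sin| over whole cycles = 2A/pi
        w = sine_window(freq=3, amp=1.2)
        _, dyn = split_static_dynamic(w)
        per_axis, total = odba(dyn)
        assert per_axis[2] == pytest.approx(2 * 1.2 / np.pi, rel=0.01)
        assert total == pytest.approx(per_axis.sum())


class TestDominantSpectrum:
    def test_bin_aligned_sinusoid(self):
        t = np.arange(128) / 64
        df, amp = dominant_spectrum(np.sin(2 * np.pi * 3 * t), fs=64)
        assert df == 3.0
        assert amp == pytest.approx(1.0, rel=1e-9)

    def test_zero_signal_tie_breaks_low(self):
        df, amp = dominant_spectrum(np.zeros(128), fs=64)
        assert df == 0.5  # lowest non-DC bin wins all-zero ties
        assert amp == 0.0

    def test_dominance_of_larger_component(self):
        t = np.arange(128) / 64
        sig = 0.3 * np.sin(2 * np.pi * 1 * t) + 1.0 * np.sin(2 * np.pi * 4 * t)
        df, amp = dominant_spectrum(sig, fs=64)
        assert df == 4.0
        assert amp == pytest.approx(1.0, rel=1e-9)

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            dominant_spectrum(np.zeros(3), fs=64)


class TestExtractFeatures:
    def test_constant_window_all_zero(self):
        row = extract_features(sine_window(amp=0.0, offset=(0.2, 0.1, 0.9)))
        for col in FEATURE_COLUMNS:
            if col.startswith("DF"):
                assert row[col] == 0.5  # tie default
            else:
                assert row[col] == pytest.approx(0.0, abs=1e-12)
        assert row["mag_range"] == pytest.approx(0.0, abs=1e-12)

    def test_high_move_closed_forms(self):
        params = syn.BehaviorParams("high_move", 3.0, 1.5, 1e-12)
        trace = syn.gen_behavior_trace(params, 2, fs=64, seed=0)
        row = extract_features(segment(trace)[0])
        assert row["DF_Z"] == 3.0
        assert row["Amp_Z"] == pytest.approx(1.5, rel=0.01)
        assert row["SD_Z"] == pytest.approx(1.5 / np.sqrt(2), rel=0.01)

    def test_schema_16_predictors(self, small_dataset):
        feats = features_frame(small_dataset.trace)
        assert len(FEATURE_COLUMNS) == 16
        assert [c for c in feats.columns if c in FEATURE_COLUMNS] == FEATURE_COLUMNS

    def test_odba_additivity_and_df_bounds(self, small_dataset):
        feats = features_frame(small_dataset.trace)
        assert np.allclose(
            feats["ODBA"], feats[["ODBA_X", "ODBA_Y", "ODBA_Z"]].sum(axis=1), atol=1e-12
        )
        for ax in ("X", "Y", "Z", "M"):
            assert (feats[f"DF_{ax}"] > 0).all()
            assert (feats[f"DF_{ax}"] <= 32).all()

    def test_vectorised_matches_per_window(self, small_dataset):
        feats = features_frame(small_dataset.trace)
        wins = segment(small_dataset.trace)
        for k in (0, 7, 101):
            row = extract_features(wins[k])
            for col in FEATURE_COLUMNS + ["mag_range"]:
                assert row[col] == pytest.approx(feats.iloc[k][col], rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        ox=st.floats(-2, 2), oy=st.floats(-2, 2), oz=st.floats(-2, 2),
        seed=st.integers(0, 1000),
    )
    def test_axis_predictors_invariant_to_any_constant_offset(self, ox, oy, oz, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 0.3, size=(128, 3))
        w0 = Window(pd.Timestamp("2020-01-01"), 64, data)
        w1 = Window(pd.Timestamp("2020-01-01"), 64, data + np.array([ox, oy, oz]))
        r0, r1 = extract_features(w0), extract_features(w1)
        axis_cols = [c for c in FEATURE_COLUMNS if not c.endswith("_M") and c != "ODBA"]
        axis_cols += ["ODBA"]  # sum of the three per-axis ODBAs
        for col in axis_cols:
            assert r1[col] == pytest.approx(r0[col], rel=1e-9, abs=1e-12)


class TestDownsample:
    def test_decimation_keeps_every_other_sample(self, rest_trace):
        out = downsample(rest_trace, 32)
        assert len(out) == len(rest_trace) // 2
        assert np.array_equal(out.data, rest_trace.data[::2])

    def test_dominant_frequency_survives_below_nyquist(self):
        params = syn.BehaviorParams("high_move", 3.0, 1.5, 1e-12)
        trace = syn.gen_behavior_trace(params, 2, fs=64, seed=0)
        out = downsample(trace, 16)
        _, dyn = split_static_dynamic(out.data)
        df, _ = dominant_spectrum(dyn[:, 2], fs=16)
        assert df == 3.0

    def test_non_divisor_rejected(self, rest_trace):
        with pytest.raises(ValueError):
            downsample(rest_trace, 48)

    def test_antialias_variant_runs(self, rest_trace):
        out = downsample(rest_trace, 16, antialias=True)
        assert out.fs == 16
        assert len(out) == len(rest_trace) // 4
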