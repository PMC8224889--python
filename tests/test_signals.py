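"""Container invariants and pre-treatment operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfkit import (
    PretreatmentConfig,
    TimeSeries,
    boxcar,
    crop,
    median_filter,
    pretreat,
    resample,
    savgol_smooth,
)


class TestTimeSeries:
    def test_validation_rejects_bad_series(self):
        with pytest.raises(ValueError):
            TimeSeries([0.0], [1.0])  # too short
        with pytest.raises(ValueError):
            TimeSeries([0.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # not increasing
        with pytest.raises(ValueError):
            TimeSeries([0.0, 1.0], [1.0, np.nan])  # non-finite value
        with pytest.raises(ValueError):
            TimeSeries([0.0, 1.0, 2.0], [1.0, 2.0])  # length mismatch

    def test_dt_defined_only_on_uniform_grids(self):
        assert TimeSeries([0.0, 0.5, 1.0], [1, 2, 3]).dt == pytest.approx(0.5)
        assert TimeSeries([0.0, 0.5, 1.2], [1, 2, 3]).dt is None

    def test_values_are_frozen(self, uniform_series):
        with pytest.raises(ValueError):
            uniform_series.values[0] = 99.0


class TestResample:
    def test_identity_on_matching_grid(self):
        ts = TimeSeries(0.05 * np.arange(50), np.sin(np.arange(50.0)))
        out = resample(ts, 0.05)
        assert np.array_equal(out.values, ts.values)

    def test_output_spacing_is_uniform(self, ramp_series):
        out = resample(ramp_series, 0.05)
        assert np.allclose(np.diff(out.times), 0.05)

    def test_linear_signal_interpolated_exactly(self, ramp_series):
        out = resample(ramp_series, 0.17)
        assert np.allclose(out.values, 2.0 * out.times, atol=1e-12)

    def test_idempotent(self, ramp_series):
        once = resample(ramp_series, 0.05)
        twice = resample(once, 0.05)
        assert np.array_equal(once.values, twice.values)
        assert np.array_equal(once.times, twice.times)

    @pytest.mark.parametrize("dt", [0.0, -0.1, 100.0])
    def test_invalid_dt_rejected(self, ramp_series, dt):
        with pytest.raises(ValueError):
            resample(ramp_series, dt)


class TestCrop:
    def test_full_span_is_identity(self, uniform_series):
        out = crop(uniform_series, uniform_series.times[0], uniform_series.times[-1])
        assert np.array_equal(out.times, uniform_series.times)
        assert np.array_equal(out.values, uniform_series.values)

    def test_closed_interval_sample_count(self):
        ts = TimeSeries(np.arange(11.0), np.arange(11.0))
        out = crop(ts, 2.0, 5.0)
        assert np.array_equal(out.times, [2.0, 3.0, 4.0, 5.0])

    def test_reversed_window_rejected(self, uniform_series):
        with pytest.raises(ValueError):
            crop(uniform_series, 5.0, 2.0)

    def test_empty_window_names_offender(self, uniform_series):
        with pytest.raises(ValueError, match="crop window"):
            crop(uniform_series, 100.0, 101.0)

    def test_commutes_with_resample_on_aligned_window(self):
        rng = np.random.default_rng(0)
        ts = TimeSeries(0.1 * np.arange(100), rng.normal(size=100))
        a = resample(crop(ts, 1.0, 5.0), 0.2)
        b = crop(resample(ts, 0.2), 1.0, 5.0)
        assert np.allclose(a.times, b.times)
        assert np.allclose(a.values, b.values)


def _brute_force_savgol(values, window, order):
    """Independent oracle: explicit local polynomial fit per sample."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = np.arange(lo, hi, dtype=float) - i
        deg = min(order, hi - lo - 1)
        V = np.vander(x, deg + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, values[lo:hi], rcond=None)
        out[i] = coef[0]
    return out


class TestSavgol:
    def test_quadratic_is_reproduced(self):
        t = 0.1 * np.arange(60)
        ts = TimeSeries(t, 3.0 * t**2 - t + 0.5)
        out = savgol_smooth(ts, window=11, order=2)
        assert np.allclose(out.values, ts.values, atol=1e-9)

    def test_constant_unchanged(self):
        ts = TimeSeries(0.1 * np.arange(20), np.full(20, 7.0))
        out = savgol_smooth(ts, window=5, order=1)
        assert np.allclose(out.values, 7.0)

    def test_reduces_noise_and_matches_brute_force(self):
        rng = np.random.default_rng(7)
        t = 0.05 * np.arange(300)
        clean = np.sin(2 * np.pi * 0.3 * t)
        noisy = clean + 0.2 * rng.normal(size=t.size)
        ts = TimeSeries(t, noisy)
        out = savgol_smooth(ts, window=15, order=3)
        rmse_raw = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_smooth = np.sqrt(np.mean((out.values - clean) ** 2))
        assert rmse_smooth < rmse_raw
        oracle = _brute_force_savgol(noisy, 15, 3)
        assert np.allclose(out.values, oracle, atol=1e-8)

    def test_nonuniform_grid_instructs_resampling(self, ramp_series):
        with pytest.raises(ValueError, match="[Rr]esample"):
            savgol_smooth(ramp_series, window=5, order=2)

    def test_preserves_length_and_times(self, uniform_series):
        out = savgol_smooth(uniform_series, window=9, order=2)
        assert np.array_equal(out.times, uniform_series.times)


class TestMedianFilter:
    def test_single_spike_removed(self):
        values = np.full(20, 3.0)
        values[10] = 50.0
        out = median_filter(TimeSeries(np.arange(20.0), values), 3)
        assert np.allclose(out.values, 3.0)

    def test_monotone_interior_unchanged(self):
        ts = TimeSeries(np.arange(10.0), np.arange(10.0) ** 2)
        out = median_filter(ts, 3)
        assert np.array_equal(out.values[1:-1], ts.values[1:-1])

    def test_matches_brute_force_sliding_median(self, uniform_series):
        out = median_filter(uniform_series, 5)
        v = uniform_series.values
        n = len(v)
        for i in range(n):
            k = min(2, i, n - 1 - i)
            assert out.values[i] == np.median(v[i - k : i + k + 1])

    def test_even_window_rejected(self, uniform_series):
        with pytest.raises(ValueError):
            median_filter(uniform_series, 4)


class TestBoxcar:
    def test_zero_duration_is_all_zero(self):
        ts = boxcar(1.0, 0.0, 0.5, 4.0)
        assert np.all(ts.values == 0.0)

    def test_half_open_interval_sample_count(self):
        ts = boxcar(1.0, 2.0, 0.5, 4.0)
        on = ts.times[ts.values == 1.0]
        assert np.array_equal(on, [1.0, 1.5, 2.0, 2.5])

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            boxcar(1.0, -0.5, 0.5, 4.0)

    @given(
        onset_steps=st.integers(min_value=0, max_value=20),
        dur_steps=st.integers(min_value=0, max_value=30),
    )
    @settings(deadline=None, max_examples=50)
    def test_riemann_sum_equals_duration(self, onset_steps, dur_steps):
        dt = 0.1
        onset, duration = onset_steps * dt, dur_steps * dt
        total = onset + duration + 1.0
        ts = boxcar(onset, duration, dt, total)
        assert ts.values.sum() * dt == pytest.approx(duration, abs=1e-9)


class TestPretreat:
    def test_chain_applies_all_configured_steps(self):
        rng = np.random.default_rng(3)
        t = 0.02 * np.arange(500)
        ts = TimeSeries(t, rng.normal(size=500).cumsum())
        cfg = PretreatmentConfig(
            dt=0.1, crop_start=1.0, crop_end=9.0, savgol_window=7,
            savgol_order=2, median_window=3,
        )
        out = pretreat(ts, cfg)
        assert out.dt == pytest.approx(0.1)
        assert out.times[0] >= 1.0 and out.times[-1] <= 9.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PretreatmentConfig(savgol_window=4)
        with pytest.raises(ValueError):
            PretreatmentConfig(savgol_window=5, savgol_order=5)
        with pytest.raises(ValueError):
            PretreatmentConfig(crop_start=5.0, crop_end=1.0)

    def test_operations_do_not_mutate_inputs(self, uniform_series):
        before = uniform_series.values.copy()
        pretreat(
            uniform_series,
            PretreatmentConfig(dt=0.1, median_window=3, savgol_window=5),
        )
        assert np.array_equal(uniform_series.values, before)
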