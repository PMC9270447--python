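"""Aging curves, P_ac, pattern classification and periodicity detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agebench import classify_pattern, detect_periodicity, moving_percentiles, p_accurate
from agebench.aging_stats import AgingCurve, BandwidthError


def _curve(dt, p50, iqr=0.2, counts=50):
    dt = np.asarray(dt, dtype=float)
    p50 = np.asarray(p50, dtype=float)
    iqr = np.broadcast_to(np.asarray(iqr, dtype=float), p50.shape)
    return AgingCurve(
        dt_grid=dt,
        p25=p50 - iqr / 2,
        p50=p50,
        p75=p50 + iqr / 2,
        counts=np.full(len(dt), counts),
        bandwidth_days=float(dt[1] - dt[0]) * 2,
    )


class TestMovingPercentiles:
    def test_constant_cloud_gives_flat_unit_curves(self):
        dt = np.linspace(0, 500, 400)
        curve = moving_percentiles((dt, np.ones(400)))
        np.testing.assert_allclose(curve.p25, 1.0)
        np.testing.assert_allclose(curve.p50, 1.0)
        np.testing.assert_allclose(curve.p75, 1.0)

    def test_linear_interpolation_convention(self):
        curve = moving_percentiles(
            ([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]),
            bandwidth_days=10.0, grid_step_days=10.0, min_count=4,
        )
        assert curve.p50[0] == 2.5

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(0)
        dt = rng.uniform(-14, 900, 10_000)
        e = rng.lognormal(0, 0.5, 10_000)
        curve = moving_percentiles((dt, e))
        half = curve.bandwidth_days / 2
        for g, p25, p50, p75 in zip(curve.dt_grid, curve.p25, curve.p50, curve.p75):
            vals = np.sort(e[np.abs(dt - g) <= half])
            assert p25 == np.percentile(vals, 25)
            assert p50 == np.percentile(vals, 50)
            assert p75 == np.percentile(vals, 75)
        assert np.all(curve.p25 <= curve.p50) and np.all(curve.p50 <= curve.p75)

    def test_all_bins_under_floor_raises(self):
        with pytest.raises(BandwidthError):
            moving_percentiles((np.arange(10.0), np.ones(10)), min_count=50)


class TestPAccurate:
    def test_all_accurate_suite(self):
        dt = np.linspace(0, 300, 500)
        pac = p_accurate((dt, np.ones(500)))
        np.testing.assert_allclose(pac.p_ac, 1.0)

    def test_half_accurate_bin(self):
        pac = p_accurate(([10.0, 20.0], [1.5, 2.5]), bin_days=30)
        assert pac.p_ac[0] == 0.5

    def test_exact_threshold_counts_as_inaccurate(self):
        pac = p_accurate(([10.0], [2.0]), bin_days=30)
        assert pac.p_ac[0] == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_only_threshold_crossing_matters(self, seed):
        rng = np.random.default_rng(seed)
        dt = rng.uniform(0, 300, 200)
        e = rng.lognormal(0.3, 0.6, 200)
        relabeled = np.where(e < 2.0, 0.5, 5.0)  # monotone collapse preserving crossings
        a = p_accurate((dt, e))
        b = p_accurate((dt, relabeled))
        np.testing.assert_array_equal(a.p_ac, b.p_ac)


class TestClassifyPattern:
    def test_flat_curve_is_stable(self):
        lab = classify_pattern(_curve(np.linspace(0, 600, 30), np.ones(30)))
        assert lab.label == "stable"

    def test_linear_growth_is_gradual(self):
        lab = classify_pattern(_curve(np.linspace(0, 600, 30), np.linspace(1, 2, 30)))
        assert lab.label == "gradual"

    def test_step_to_high_plateau_is_explosive_with_changepoint(self):
        dt = np.linspace(0, 600, 30)
        p50 = np.where(dt < 300, 1.0, 12.0)
        lab = classify_pattern(_curve(dt, p50))
        assert lab.label == "explosive"
        assert abs(lab.evidence["changepoint_day"] - 300) <= (dt[1] - dt[0]) + 1e-9

    def test_widening_band_with_flat_median_is_variability_growth(self):
        dt = np.linspace(0, 600, 30)
        lab = classify_pattern(_curve(dt, np.ones(30), iqr=np.linspace(0.2, 0.8, 30)))
        assert lab.label == "variability_growth"

    @pytest.mark.parametrize("stretch", [0.1, 3.0])
    def test_label_invariant_to_time_axis_stretch(self, stretch):
        dt = np.linspace(0, 600, 30)
        for p50, iqr, expected in [
            (np.ones(30), 0.2, "stable"),
            (np.linspace(1, 2, 30), 0.2, "gradual"),
            (np.where(dt < 300, 1.0, 12.0), 0.2, "explosive"),
            (np.ones(30), np.linspace(0.2, 0.8, 30), "variability_growth"),
        ]:
            assert classify_pattern(_curve(dt * stretch, p50, iqr=iqr)).label == expected

    def test_requires_ten_bins(self):
        with pytest.raises(ValueError, match="10"):
            classify_pattern(_curve(np.linspace(0, 90, 5), np.ones(5)))


class TestPeriodicity:
    def test_recovers_annual_cycle(self):
        dt = np.arange(0, 1460, 10.0)
        curve = _curve(dt, 1 + 0.5 * np.sin(2 * np.pi * dt / 365))
        rep = detect_periodicity(curve, seed=0)
        assert rep.significance_p < 0.01
        assert rep.dominant_period_days == pytest.approx(365, abs=5)
        # FFT oracle on the evenly spaced curve
        freqs = np.fft.rfftfreq(len(dt), d=10.0)
        spectrum = np.abs(np.fft.rfft(curve.p50 - curve.p50.mean()))
        fft_period = 1 / freqs[np.argmax(spectrum[1:]) + 1]
        assert rep.dominant_period_days == pytest.approx(fft_period, rel=0.05)

    def test_constant_curve_has_no_dominant_period(self):
        rep = detect_periodicity(_curve(np.arange(0, 1460, 10.0), np.ones(146)), seed=0)
        assert rep.dominant_period_days is None
        assert rep.significance_p >= 0.05

    def test_pure_trend_removed_before_analysis(self):
        dt = np.arange(0, 1460, 10.0)
        rep = detect_periodicity(_curve(dt, 1 + dt / 1000), seed=0)
        assert rep.dominant_period_days is None

    def test_short_curve_clips_period_range_with_warning(self):
        dt = np.arange(0, 400, 10.0)
        with pytest.warns(UserWarning, match="clipping"):
            detect_periodicity(_curve(dt, 1 + 0.3 * np.sin(2 * np.pi * dt / 90)), seed=0)

    @pytest.mark.parametrize("period", [90.0, 182.0, 365.0])
    def test_recovery_rate_across_seeds(self, period):
        dt = np.arange(0, 1460, 15.0)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p50 = 1 + 0.3 * np.sin(2 * np.pi * dt / period + rng.uniform(0, 2 * np.pi))
            p50 = p50 + 0.1 * rng.standard_normal(len(dt))
            rep = detect_periodicity(_curve(dt, p50), n_permutations=200, seed=seed)
            if rep.dominant_period_days and abs(rep.dominant_period_days - period) <= 0.05 * period:
                hits += 1
        assert hits >= 18  # >= 90% recovery
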