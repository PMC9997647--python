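"""Detrending, robust averaging and signal statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrobomb.chronology import (
    biweight_mean,
    build_chronology,
    detrend_spline,
    eps_sss,
    interseries_correlation,
    mean_sensitivity,
    segment_lag_flags,
)
from dendrobomb.types import RingWidthSeries

from conftest import make_common_signal_series, make_noise_series


def sinusoid_series(period, amplitude=0.2, mean=1.0, n=300, sid="SIN01A"):
    years = np.arange(n)
    return RingWidthSeries(
        sid, 1700, tuple(mean + amplitude * np.sin(2 * np.pi * years / period))
    )


def fitted_amplitude(series, result, period):
    """Amplitude of the fitted curve at the test period, interior 200 yr."""
    interior = slice(50, 250)
    t = np.arange(len(series))[interior]
    f = result.fitted[interior]
    f = f - f.mean()
    a = 2 * np.mean(f * np.sin(2 * np.pi * t / period))
    b = 2 * np.mean(f * np.cos(2 * np.pi * t / period))
    return float(np.hypot(a, b))


class TestDetrendSpline:
    def test_constant_series_reproduced(self):
        s = RingWidthSeries("CST01A", 1950, (1.0,) * 60)
        d = detrend_spline(s)
        np.testing.assert_allclose(d.fitted, 1.0, atol=1e-6)
        np.testing.assert_allclose(d.index, 1.0, atol=1e-6)

    def test_half_amplitude_at_cutoff_period(self):
        s = sinusoid_series(period=30)
        amp = fitted_amplitude(s, detrend_spline(s, 30), 30)
        assert amp == pytest.approx(0.10, abs=0.006)

    def test_long_waves_pass_into_trend(self):
        s = sinusoid_series(period=300)
        amp = fitted_amplitude(s, detrend_spline(s, 30), 300)
        assert amp >= 0.19

    def test_short_waves_rejected(self):
        s = sinusoid_series(period=3, amplitude=0.2)
        amp = fitted_amplitude(s, detrend_spline(s, 30), 3)
        assert amp <= 0.05 * 0.2 / 0.5  # <= 5% response on the 0.2 amplitude

    def test_index_scale_invariant(self, rng):
        s = make_noise_series(rng, n=120)
        scaled = RingWidthSeries(s.series_id, s.first_year, tuple(3.7 * s.values))
        np.testing.assert_allclose(
            detrend_spline(s).index, detrend_spline(scaled).index, atol=1e-9
        )

    def test_zero_width_gives_zero_index(self, rng):
        w = list(make_noise_series(rng, n=60).values)
        w[30] = 0.0
        d = detrend_spline(RingWidthSeries("Z", 1900, tuple(w)))
        assert d.index[30] == 0.0
        assert np.all(d.fitted > 0)

    def test_too_short_or_all_zero_rejected(self):
        with pytest.raises(ValueError, match="short"):
            detrend_spline(RingWidthSeries("S", 1900, (1.0,) * 5))
        with pytest.raises(ValueError, match="all-zero"):
            detrend_spline(RingWidthSeries("S", 1900, (0.0,) * 40))


class TestBiweightMean:
    def test_equal_values(self):
        assert biweight_mean([1.0, 1.0, 1.0]) == 1.0

    def test_symmetric(self):
        assert biweight_mean([0.8, 1.0, 1.2]) == pytest.approx(1.0, abs=1e-9)

    def test_outlier_suppressed(self):
        # arithmetic mean is 2.8; the robust location stays near 1
        assert biweight_mean([1.0, 1.0, 1.0, 1.0, 10.0]) == pytest.approx(1.0, abs=0.05)

    def test_matches_hand_iterated_tukey(self):
        # independent oracle: explicit loop, no shared code path
        x = np.array([0.9, 1.0, 1.1, 1.3, 2.5])
        m = np.median(x)
        mad = np.median(np.abs(x - m))
        for _ in range(200):
            u = (x - m) / (9 * mad)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            m = np.sum(w * x) / np.sum(w)
        assert biweight_mean(x) == pytest.approx(m, abs=1e-7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            biweight_mean([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30))
    def test_bounded_by_min_max(self, values):
        m = biweight_mean(values)
        assert min(values) - 1e-9 <= m <= max(values) + 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.integers(1, 20))
    def test_zero_spread_equals_arithmetic_mean(self, v, n):
        assert biweight_mean([v] * n) == pytest.approx(v, abs=1e-12)


class TestMeanSensitivity:
    def test_constant_is_zero(self):
        assert mean_sensitivity(RingWidthSeries("C", 1900, (2.0,) * 20)) == 0.0

    def test_alternating_is_one(self):
        s = RingWidthSeries("A", 1900, (1.0, 3.0) * 10)
        assert mean_sensitivity(s) == pytest.approx(1.0)

    def test_hand_value(self):
        s = RingWidthSeries("H", 1900, (1.0, 2.0, 4.0))
        assert mean_sensitivity(s) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_consecutive_zeros_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            mean_sensitivity(RingWidthSeries("Z", 1900, (1.0, 0.0, 0.0, 1.0)))


class TestEpsSss:
    def test_perfect_common_signal(self):
        eps, sss = eps_sss(1.0, 10, [1, 5, 10])
        assert eps == 1.0
        np.testing.assert_allclose(sss, 1.0)

    def test_formula_value(self):
        eps, _ = eps_sss(0.25, 10, [10])
        assert eps == pytest.approx(10 * 0.25 / (1 + 9 * 0.25), abs=1e-12)

    def test_grid_against_independent_arithmetic(self):
        # oracle: algebraically rearranged forms coded independently
        for rbar in (0.05, 0.2, 0.5, 0.531, 0.8, 0.95):
            for n in (2, 5, 10, 23):
                eps, sss = eps_sss(rbar, n, np.arange(1, n + 1))
                eps_alt = rbar / (rbar + (1.0 - rbar) / n)
                assert eps == pytest.approx(eps_alt, abs=1e-12)
                for m in range(1, n + 1):
                    num = m * (1 / rbar + (n - 1))
                    den = n * (1 / rbar + (m - 1))
                    assert sss[m - 1] == pytest.approx(num / den, abs=1e-12)
                assert sss[-1] == pytest.approx(1.0, abs=1e-12)

    def test_sss_monotone_in_depth(self):
        _, sss = eps_sss(0.25, 10, np.arange(1, 11))
        assert np.all(np.diff(sss) >= -1e-15)

    def test_zero_rbar(self):
        eps, _ = eps_sss(0.0, 10, [5])
        assert eps == 0.0

    def test_invalid_rbar(self):
        with pytest.raises(ValueError):
            eps_sss(1.5, 10, [5])


class TestBuildChronology:
    def test_identical_series(self, rng):
        s = make_noise_series(rng, "TWIN01A", n=120)
        s2 = RingWidthSeries("TWIN02A", s.first_year, s.widths)
        ch = build_chronology([s, s2])
        d = detrend_spline(s)
        np.testing.assert_allclose(ch.index, d.index, atol=1e-9)
        assert ch.rbar == pytest.approx(1.0, abs=1e-9)
        assert ch.eps == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_rbar_near_zero(self, rng):
        a = make_noise_series(rng, "WNA01", n=100)
        b = make_noise_series(rng, "WNB01", n=100)
        ch = build_chronology([a, b])
        assert abs(ch.rbar) < 0.25

    def test_common_signal_eps(self, rng):
        series = make_common_signal_series(rng, pair_r=0.5)
        ch = build_chronology(series)
        assert ch.eps > 0.8

    def test_depth_conservation(self, rng):
        series = [
            make_noise_series(rng, f"D{i}", first_year=1900 + 10 * i, n=80)
            for i in range(4)
        ]
        ch = build_chronology(series)
        assert ch.sample_depth.sum() == sum(len(s) for s in series)
        assert ch.sample_depth.max() <= len(series)

    def test_no_overlap_rejected(self, rng):
        a = make_noise_series(rng, "A", first_year=1800, n=50)
        b = make_noise_series(rng, "B", first_year=1950, n=50)
        with pytest.raises(ValueError, match="overlap"):
            build_chronology([a, b])


class TestInterseriesCorrelation:
    def test_duplicated_series(self, rng):
        s = make_noise_series(rng, n=100)
        s2 = RingWidthSeries("COPY01A", s.first_year, s.widths)
        rep = interseries_correlation([s, s2])
        assert rep.overall == pytest.approx(1.0, abs=1e-9)

    def test_negated_series_anticorrelated(self, rng):
        s = make_noise_series(rng, n=100)
        neg = RingWidthSeries("NEG01A", s.first_year, tuple(2.0 - s.values))
        rep = interseries_correlation([s, neg])
        assert rep.overall <= -0.99

    def test_known_common_signal_level(self, rng):
        # pairwise r = 0.345 makes the correlation of one series with the
        # mean of the 5 others 0.345/sqrt(0.345 + 0.655/5) ~= 0.5
        reps = [
            interseries_correlation(
                make_common_signal_series(rng, pair_r=0.345, n=150)
            ).overall
            for _ in range(10)
        ]
        assert np.mean(reps) == pytest.approx(0.5, abs=0.1)


class TestSegmentLagFlags:
    def _master(self, rng):
        series = make_common_signal_series(rng, n_series=4, pair_r=0.6, n=150)
        return series, build_chronology(series)

    def test_self_series_unflagged(self, rng):
        series, master = self._master(rng)
        rep = segment_lag_flags(series[0], master)
        assert rep.flags == []

    def test_deleted_rings_flag_outer_segments(self, rng):
        series, master = self._master(rng)
        s = series[0]
        # delete 5 mid-series rings: the outer part now sits 5 yr too recent
        w = list(s.values)
        cut = 100
        del w[cut : cut + 5]
        shifted = RingWidthSeries("SHIFT01", s.first_year + 5, tuple(w))
        rep = segment_lag_flags(shifted, master, flag_margin=0.05)
        lags = {f.suggested_lag for f in rep.flags}
        assert any(l == -5 for l in lags) or any(l == 5 for l in lags)

    def test_white_noise_rarely_flagged(self, rng):
        _, master = self._master(rng)
        n_flagged = 0
        for i in range(100):
            noise = make_noise_series(rng, f"WN{i:03d}", first_year=1890, n=150)
            rep = segment_lag_flags(noise, master)
            n_flagged += bool(rep.flags)
        assert n_flagged <= 5
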