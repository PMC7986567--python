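"""Differencing, transforms, correlograms and the ADF unit-root test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itsarima import (TimeSeries, acf, adf_test, difference, log_transform,
                      pacf, simulate_from)
from itsarima.sarima import ArimaOrder


class TestDifference:
    def test_constant_series_differences_to_zero(self):
        out = difference(TimeSeries([5.0] * 4, period=1), lag=1)
        np.testing.assert_allclose(out.values, [0.0, 0.0, 0.0])

    def test_linear_trend_differences_to_constant(self):
        out = difference(TimeSeries([1.0, 2, 3, 4, 5], period=1), lag=1)
        np.testing.assert_allclose(out.values, np.ones(4))

    def test_seasonal_difference_of_periodic_pattern(self):
        pattern = np.sin(2 * np.pi * np.arange(12) / 12) * 5 + 10
        ts = TimeSeries(np.tile(pattern, 2), period=12)
        out = difference(ts, lag=12)
        assert out.n == 24 - 12     # the first year is lost
        np.testing.assert_allclose(out.values, np.zeros(12), atol=1e-12)

    def test_start_advances_with_calendar(self):
        ts = TimeSeries.monthly(np.arange(30.0), start="2011-01")
        out = difference(ts, lag=12)
        assert str(out.index[0]) == "2012-01"

    def test_too_short_names_required_length(self):
        with pytest.raises(ValueError, match="insufficient observations.*13"):
            difference(TimeSeries(np.arange(10.0), period=12), lag=12)

    def test_difference_operators_commute(self, rng):
        x = TimeSeries(rng.normal(size=60).cumsum(), period=12)
        a = difference(difference(x, 1), 12)
        b = difference(difference(x, 12), 1)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestLogTransform:
    def test_known_values(self):
        ts = TimeSeries([1.0, np.e, np.e ** 2], period=1)
        np.testing.assert_allclose(log_transform(ts).values, [0, 1, 2],
                                   atol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="strictly positive"):
            log_transform(TimeSeries([1.0, 0.0, 2.0], period=1))

    def test_records_transform_and_inverts(self, rng):
        vals = np.exp(rng.normal(size=50))
        ts = TimeSeries(vals, period=1)
        logged = log_transform(ts)
        assert logged.transform == "log"
        np.testing.assert_allclose(np.exp(logged.values), vals, rtol=1e-12)


class TestAcf:
    def test_lag_zero_is_one_and_bounded(self, white_noise_series):
        r = acf(white_noise_series, max_lag=20)
        assert r.values[0] == 1.0
        assert np.all(np.abs(r.values) <= 1.0 + 1e-12)

    def test_ar1_acf_decays_geometrically(self):
        ts = simulate_from(ArimaOrder(1, 0, 0), 5000, seed=11, phi=[0.6])
        r = acf(ts, max_lag=5)
        np.testing.assert_allclose(r.values[1:], 0.6 ** np.arange(1, 6),
                                   atol=0.05)

    def test_white_noise_band_holds_about_95pct(self):
        rng = np.random.default_rng(5)
        inside = []
        for _ in range(25):
            ts = TimeSeries(rng.normal(size=2000), period=1)
            r = acf(ts, max_lag=20)
            inside.append(np.abs(r.values[1:]) < r.ci_bound)
        frac = np.mean(inside)
        assert 0.90 < frac <= 1.0

    def test_max_lag_too_large(self, white_noise_series):
        with pytest.raises(ValueError, match="max_lag"):
            acf(white_noise_series, max_lag=white_noise_series.n)


class TestPacf:
    def test_lag1_pacf_equals_lag1_acf(self, white_noise_series):
        assert pacf(white_noise_series, 5).values[1] == pytest.approx(
            acf(white_noise_series, 5).values[1], abs=1e-12)

    def test_ar1_pacf_cuts_off_after_lag_one(self):
        ts = simulate_from(ArimaOrder(1, 0, 0), 5000, seed=12, phi=[0.6])
        v = pacf(ts, max_lag=5).values
        assert v[1] == pytest.approx(0.6, abs=0.05)
        np.testing.assert_allclose(v[2:], 0.0, atol=0.05)

    def test_ma1_acf_cuts_off_while_pacf_tails(self):
        ts = simulate_from(ArimaOrder(0, 0, 1), 5000, seed=13, theta=[0.7])
        ra = acf(ts, max_lag=6).values
        rp = pacf(ts, max_lag=6).values
        assert abs(ra[1]) > 0.3
        np.testing.assert_allclose(ra[2:], 0.0, atol=0.05)
        # PACF of an MA(1) decays geometrically, still visible at lag 2
        assert abs(rp[2]) > 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_durbin_levinson_matches_regression_definition(self, seed, k):
        """phi_kk equals the last coefficient of Y_t ~ Y_{t-1}..Y_{t-k}
        when the regression uses the same Toeplitz autocorrelations."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=150).cumsum() * 0.1 + rng.normal(size=150)
        ts = TimeSeries(x, period=1)
        r = acf(ts, max_lag=k).values
        R = np.array([[r[abs(i - j)] for j in range(k)] for i in range(k)])
        phi = np.linalg.solve(R, r[1:k + 1])
        assert pacf(ts, max_lag=k).values[k] == pytest.approx(phi[-1],
                                                              abs=1e-10)


class TestAdf:
    def test_white_noise_rejects_unit_root(self):
        reject = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            res = adf_test(TimeSeries(rng.normal(size=500), period=1))
            reject += res.reject_unit_root
        assert reject >= 36          # >= 90% power against white noise

    def test_random_walk_fails_to_reject(self):
        keep = 0
        for seed in range(40):
            rng = np.random.default_rng(seed + 1000)
            walk = rng.normal(size=500).cumsum()
            res = adf_test(TimeSeries(walk, period=1))
            keep += not res.reject_unit_root
        assert keep >= 36            # size: retain the null >= 90%

    def test_constant_series_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            adf_test(TimeSeries([3.0] * 50, period=1))

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="too short"):
            adf_test(TimeSeries([1.0, 2.0, 1.5], period=1))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_acf_values_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=rng.integers(20, 80)) * rng.uniform(0.1, 50)
    r = acf(TimeSeries(x, period=1), max_lag=10)
    assert r.values[0] == 1.0
    assert np.all(np.abs(r.values) <= 1.0 + 1e-12)
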