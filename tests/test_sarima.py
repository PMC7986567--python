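"""Maximum-likelihood SARIMA estimation, forecasting and simulation."""

import numpy as np
import pytest

from itsarima import (ArimaOrder, InterventionSpec, TimeSeries, fit, forecast,
                      simulate_from)
from itsarima import _statespace as ss


class TestArimaOrder:
    def test_parse_and_str(self):
        o = ArimaOrder.parse("(2,1,0)(0,1,1)12")
        assert (o.p, o.d, o.q, o.P, o.D, o.Q, o.s) == (2, 1, 0, 0, 1, 1, 12)
        assert str(o) == "(2,1,0)(0,1,1)[12]"
        assert str(ArimaOrder.parse("1,0,0")) == "(1,0,0)"

    def test_rejects_excess_differencing(self):
        with pytest.raises(ValueError, match="d \\+ D"):
            ArimaOrder(0, 3, 0, 0, 1, 0, 12)

    def test_rejects_seasonal_terms_without_period(self):
        with pytest.raises(ValueError, match="seasonal"):
            ArimaOrder(0, 0, 0, 1, 0, 0, 1)


class TestLikelihoodMachinery:
    @pytest.mark.parametrize("phi", [[0.5], [0.6, -0.3], [-0.45, -0.35]])
    def test_pure_ar_whitening_equals_kalman(self, phi, rng):
        """The fast AR likelihood path and the state-space path are the
        same exact likelihood."""
        w = rng.normal(size=120)
        ap = ss.ar_poly(phi, [], 1)
        bp = np.array([1.0])
        e1, ld1 = ss.ar_whiten(ap, w[:, None])
        V, F = ss.kalman_innovations(ap, bp, w[:, None])
        np.testing.assert_allclose(e1[:, 0], V[:, 0] / np.sqrt(F), atol=1e-10)
        assert ld1 == pytest.approx(np.sum(np.log(F)), abs=1e-10)

    def test_loglik_matches_statsmodels(self):
        from statsmodels.tsa.statespace.sarimax import SARIMAX
        ts = simulate_from(ArimaOrder(2, 0, 1), 150, seed=8,
                           phi=[0.5, -0.3], theta=[0.4], sigma=1.3)
        ap = ss.ar_poly([0.5, -0.3], [], 1)
        bp = ss.ma_poly([0.4], [], 1)
        mine = ss.loglik_given_all(ap, bp, ts.values, None, np.zeros(0), 1.69)
        sm = SARIMAX(ts.values, order=(2, 0, 1), trend="n").loglike(
            np.r_[0.5, -0.3, 0.4, 1.69])
        assert mine == pytest.approx(sm, abs=1e-6)


class TestFit:
    def test_white_noise_recovers_mean_and_variance(self):
        ts = simulate_from(ArimaOrder(0, 0, 0), 500, seed=1, const=10.0,
                           sigma=2.0)
        m = fit(ts, ArimaOrder(0, 0, 0))
        assert m.const == pytest.approx(ts.values.mean(), abs=1e-6)
        assert m.sigma2 == pytest.approx(ts.values.var(), rel=1e-6)

    def test_ar1_parameter_recovery_with_ci(self):
        """Across replicates the AR coefficient is unbiased and its Wald
        interval has roughly nominal coverage."""
        est, cover = [], 0
        n_rep = 60
        for seed in range(n_rep):
            ts = simulate_from(ArimaOrder(1, 0, 0), 300, seed=seed, phi=[0.5])
            m = fit(ts, ArimaOrder(1, 0, 0))
            row = m.coef_table().loc["ar1"]
            est.append(row.coef)
            cover += row.lo95 < 0.5 < row.hi95
        assert np.mean(est) == pytest.approx(0.5, abs=0.03)
        assert cover / n_rep >= 0.85

    def test_optimum_beats_truth(self):
        ts = simulate_from(ArimaOrder(1, 0, 1), 200, seed=3, phi=[0.6],
                           theta=[-0.3])
        m = fit(ts, ArimaOrder(1, 0, 1))
        ap = ss.ar_poly([0.6], [], 1)
        bp = ss.ma_poly([-0.3], [], 1)
        ll_truth, *_ = ss.profile_gls_loglik(
            ap, bp, ts.values - ts.values.mean(), None)
        assert m.loglik >= ll_truth - 1e-6

    def test_information_criteria_recomputable(self, fixture_series):
        step = InterventionSpec("step", "2014-01", label="step")
        m = fit(fixture_series, ArimaOrder(1, 1, 0, 0, 1, 1, 12), [step])
        k = m.k_params
        assert k == 4           # omega + ar1 + sma1 + sigma2
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * k)
        assert m.bic == pytest.approx(-2 * m.loglik + k * np.log(m.n_effective))
        assert m.aicc == pytest.approx(
            m.aic + 2 * k * (k + 1) / (m.n_effective - k - 1))

    def test_constant_excluded_under_differencing(self, fixture_series):
        m = fit(fixture_series, ArimaOrder(0, 1, 1, 0, 1, 0, 12))
        assert not m.include_constant
        assert m.mean == 0.0

    def test_insufficient_data_names_deficit(self):
        ts = TimeSeries.monthly(np.arange(15.0), start="2011-01")
        with pytest.raises(ValueError, match="insufficient data"):
            fit(ts, ArimaOrder(2, 1, 2, 0, 1, 1, 12))

    def test_residuals_have_effective_length(self, fixture_series):
        m = fit(fixture_series, ArimaOrder(2, 1, 0, 0, 1, 1, 12))
        assert m.residuals.n == m.n_effective == fixture_series.n - 13

    def test_estimated_polynomials_are_stable(self, fixture_series):
        m = fit(fixture_series, ArimaOrder(2, 1, 0, 0, 1, 1, 12))
        assert ss.poly_stable(ss.ar_poly(m.phi, m.seasonal_phi, 12), tol=0)
        assert ss.poly_stable(ss.ma_poly(m.theta, m.seasonal_theta, 12), tol=0)


class TestForecast:
    def test_white_noise_forecast_is_flat_mean(self):
        ts = simulate_from(ArimaOrder(0, 0, 0), 300, seed=4, const=5.0,
                           sigma=1.5)
        m = fit(ts, ArimaOrder(0, 0, 0))
        f = forecast(m, 6)
        np.testing.assert_allclose(f.mean, m.mean, atol=1e-9)
        np.testing.assert_allclose(f.hi - f.mean,
                                   1.96 * np.sqrt(m.sigma2), atol=1e-9)

    def test_ar1_closed_form(self):
        ts = simulate_from(ArimaOrder(1, 0, 0), 300, seed=5, phi=[0.7],
                           const=2.0)
        m = fit(ts, ArimaOrder(1, 0, 0))
        f = forecast(m, 8)
        phi, c = m.phi[0], m.const
        y_n = ts.values[-1]
        for h in range(1, 9):
            closed = c * (1 - phi ** h) / (1 - phi) + phi ** h * y_n
            assert f.mean[h - 1] == pytest.approx(closed, abs=1e-8)

    @pytest.mark.parametrize("order", [
        ArimaOrder(1, 0, 0), ArimaOrder(0, 1, 1),
        ArimaOrder(1, 1, 0, 0, 1, 1, 12)])
    def test_interval_width_nondecreasing(self, order):
        n = 80 if order.s == 1 else 60
        ts = simulate_from(order, n, seed=6, phi=[0.5] * order.p,
                           theta=[0.4] * order.q,
                           stheta=[-0.4] * order.Q, sigma=1.0)
        m = fit(ts, order)
        f = forecast(m, 12)
        widths = f.hi - f.lo
        assert np.all(np.diff(widths) >= -1e-9)

    def test_future_regressor_path_length_checked(self, fixture_series):
        step = InterventionSpec("step", "2014-01")
        m = fit(fixture_series, ArimaOrder(1, 1, 0, 0, 1, 1, 12), [step])
        with pytest.raises(ValueError, match="supply a value"):
            forecast(m, 6, future_interventions=np.zeros(4))


class TestSimulate:
    def test_white_noise_mean(self):
        ts = simulate_from(ArimaOrder(0, 0, 0), 10_000, seed=7, const=10.0)
        assert ts.values.mean() == pytest.approx(10.0, abs=0.05)

    def test_ar1_stationary_variance(self):
        ts = simulate_from(ArimaOrder(1, 0, 0), 20_000, seed=8, phi=[0.6])
        assert ts.values.var() == pytest.approx(1 / (1 - 0.36), rel=0.05)

    def test_seed_determinism(self):
        a = simulate_from(ArimaOrder(1, 1, 0, 0, 1, 1, 12), 48, seed=9,
                          phi=[-0.4], stheta=[-0.5])
        b = simulate_from(ArimaOrder(1, 1, 0, 0, 1, 1, 12), 48, seed=9,
                          phi=[-0.4], stheta=[-0.5])
        c = simulate_from(ArimaOrder(1, 1, 0, 0, 1, 1, 12), 48, seed=10,
                          phi=[-0.4], stheta=[-0.5])
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_unstable_parameters_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            simulate_from(ArimaOrder(1, 0, 0), 100, seed=1, phi=[1.05])
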