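"""ARIMA differencing, likelihood, estimation, and fitted values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecgvol as ev
from ecgvol.arima import ArimaOrders, coef_to_pacf, pacf_to_coef
from ecgvol.selection import information_criterion

LOG2PI = np.log(2 * np.pi)


class TestDifferencing:
    def test_first_difference_of_squares(self):
        np.testing.assert_array_equal(ev.difference([1, 4, 9, 16], 1), [3, 5, 7])

    def test_second_difference_of_quadratic_is_constant(self):
        np.testing.assert_array_equal(ev.difference([1, 4, 9, 16], 2), [2, 2])

    def test_d0_is_identity(self):
        x = np.array([3.0, -1.0, 2.0])
        np.testing.assert_array_equal(ev.difference(x, 0), x)

    def test_integrate_inverts(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        np.testing.assert_array_equal(ev.integrate([3, 5, 7], 1, [1]), x)
        np.testing.assert_array_equal(ev.integrate([2, 2], 2, [1, 4]), x)

    @pytest.mark.parametrize("d", [0, 1, 2])
    @given(x=st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=3, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_property(self, x, d):
        x = np.asarray(x)
        back = ev.integrate(ev.difference(x, d), d, x[:d])
        np.testing.assert_allclose(back, x, atol=1e-6 * (1 + np.max(np.abs(x))))

    def test_invalid_d_rejected(self):
        with pytest.raises(ValueError):
            ev.difference([1, 2, 3, 4], 3)
        with pytest.raises(ValueError):
            ev.integrate([1, 2], 1, [])


class TestPacfTransform:
    @given(r=st.lists(st.floats(min_value=-0.95, max_value=0.95), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_bijection_and_stationarity(self, r):
        r = np.asarray(r)
        a = pacf_to_coef(r)
        np.testing.assert_allclose(coef_to_pacf(a), r, atol=1e-8)
        roots = np.roots(np.concatenate([[1.0], -a]))
        assert np.all(np.abs(roots) < 1.0 + 1e-8)


class TestLoglik:
    def test_white_noise_closed_form(self):
        res = ev.arima_loglik({"ar_coeffs": [], "ma_coeffs": [], "innovation_variance": 1.0},
                              [0.0, 0.0, 0.0], ArimaOrders(0, 0, 0))
        assert res["loglik"] == pytest.approx(-1.5 * LOG2PI, abs=1e-12)

    def test_zero_coefficient_reduction(self):
        x = [0.4, -0.2, 0.7]
        base = ev.arima_loglik({"ar_coeffs": [], "ma_coeffs": [], "innovation_variance": 1.0},
                               x, ArimaOrders(0, 0, 0))
        ar0 = ev.arima_loglik({"ar_coeffs": [0.0], "ma_coeffs": [], "innovation_variance": 1.0},
                              x, ArimaOrders(1, 0, 0))
        # AR(1) with a1=0 conditions on one observation; compare term-for-term
        assert ar0["loglik"] == pytest.approx(
            base["loglik"] - (-0.5 * LOG2PI - x[0] ** 2 / 2), abs=1e-12)
        np.testing.assert_allclose(ar0["residuals"], x)

    def test_ar1_hand_recursion(self):
        # eps_1 = 1 (conditioning), eps_2 = 1 - 0.5*1 = 0.5; loglik over t=2 only
        res = ev.arima_loglik({"ar_coeffs": [0.5], "ma_coeffs": [], "innovation_variance": 1.0},
                              [1.0, 1.0], ArimaOrders(1, 0, 0))
        np.testing.assert_allclose(res["residuals"], [1.0, 0.5])
        assert res["loglik"] == pytest.approx(-0.5 * LOG2PI - 0.125, abs=1e-12)

    def test_explosive_ma_flagged_not_raised(self):
        x = np.random.default_rng(0).standard_normal(200)
        res = ev.arima_loglik({"ar_coeffs": [], "ma_coeffs": [-5.0], "innovation_variance": 1.0},
                              x, ArimaOrders(0, 0, 1))
        assert res["loglik"] == -np.inf


class TestFit:
    def test_arma11_simulation_recovery(self):
        x = ev.simulate_arima(ArimaOrders(1, 0, 1), [0.6], [0.3], 1.0, 20000, seed=42)
        fit = ev.fit_arima(x, ArimaOrders(1, 0, 1))
        assert fit.ar_coeffs[0] == pytest.approx(0.6, abs=0.05)
        assert fit.ma_coeffs[0] == pytest.approx(0.3, abs=0.05)
        assert fit.innovation_variance == pytest.approx(1.0, abs=0.05)

    def test_white_noise_variance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000) * 1.7
        fit = ev.fit_arima(x, ArimaOrders(0, 0, 0))
        assert fit.innovation_variance == pytest.approx(np.mean((x - x.mean()) ** 2),
                                                        rel=1e-12)

    def test_arima110_recovery_and_differencing_pays(self):
        x = ev.simulate_arima(ArimaOrders(1, 1, 0), [0.6], [], 1.0, 20000, seed=43)
        fit_d1 = ev.fit_arima(x, ArimaOrders(1, 1, 0))
        assert fit_d1.ar_coeffs[0] == pytest.approx(0.6, abs=0.05)
        fit_d0 = ev.fit_arima(x, ArimaOrders(1, 0, 0))
        n = x.size
        bic_d1 = information_criterion("BIC", fit_d1.n_params, n, fit_d1.loglik).value
        bic_d0 = information_criterion("BIC", fit_d0.n_params, n, fit_d0.loglik).value
        assert bic_d1 < bic_d0

    def test_loglik_at_optimum_beats_truth(self):
        x = ev.simulate_arima(ArimaOrders(1, 0, 1), [0.6], [0.3], 1.0, 4000, seed=44)
        fit = ev.fit_arima(x, ArimaOrders(1, 0, 1))
        at_truth = ev.arima_loglik(
            {"ar_coeffs": [0.6], "ma_coeffs": [0.3],
             "innovation_variance": fit.innovation_variance},
            x - x.mean(), ArimaOrders(1, 0, 1))
        assert fit.loglik >= at_truth["loglik"] - 1e-6

    def test_deterministic_given_seed(self):
        x = ev.simulate_arima(ArimaOrders(2, 0, 1), [0.5, -0.2], [0.3], 1.0, 3000, seed=45)
        a = ev.fit_arima(x, ArimaOrders(2, 0, 1))
        b = ev.fit_arima(x, ArimaOrders(2, 0, 1))
        np.testing.assert_array_equal(a.ar_coeffs, b.ar_coeffs)
        np.testing.assert_array_equal(a.ma_coeffs, b.ma_coeffs)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ev.fit_arima(np.zeros(15), ArimaOrders(2, 0, 2))

    def test_consistency_bias_shrinks_with_n(self):
        """|bias| of the AR coefficient decreases through n = 500, 2000, 20000."""
        biases = []
        for n in (500, 2000, 20000):
            errs = [ev.fit_arima(
                        ev.simulate_arima(ArimaOrders(1, 0, 1), [0.6], [0.3], 1.0, n,
                                          seed=1000 + 17 * n + s),
                        ArimaOrders(1, 0, 1)).ar_coeffs[0] - 0.6
                    for s in range(8)]
            biases.append(abs(np.mean(errs)))
        # monotone within Monte-Carlo slack at the smallest size
        assert biases[2] < biases[0] + 1e-3
        assert biases[1] < biases[0] + 5e-3
        assert biases[2] < 0.01

    def test_statsmodels_cross_check(self):
        """Independent exact-MLE oracle agrees with the CSS fit at long n."""
        import statsmodels.api as sm

        x = ev.simulate_arima(ArimaOrders(1, 0, 1), [0.6], [0.3], 1.0, 5000, seed=3)
        mine = ev.fit_arima(x, ArimaOrders(1, 0, 1))
        ref = sm.tsa.arima.ARIMA(x, order=(1, 0, 1)).fit()
        assert mine.ar_coeffs[0] == pytest.approx(ref.arparams[0], abs=0.01)
        assert mine.ma_coeffs[0] == pytest.approx(ref.maparams[0], abs=0.01)


class TestFitted:
    def test_identity_with_residuals(self):
        x = ev.simulate_arima(ArimaOrders(1, 1, 1), [0.5], [0.2], 1.0, 2000, seed=9)
        fit = ev.fit_arima(x, ArimaOrders(1, 1, 1))
        fitted = ev.arima_fitted(fit, x)
        head = 1 + 1
        np.testing.assert_array_equal(fitted[:head], x[:head])
        np.testing.assert_allclose(x[head:] - fitted[head:], fit.residuals[head - 1:])

    def test_pure_noise_predicts_mean(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        fit = ev.fit_arima(x, ArimaOrders(0, 0, 0))
        fitted = ev.arima_fitted(fit, x)
        np.testing.assert_allclose(fitted, x - fit.residuals, atol=1e-12)
        np.testing.assert_allclose(fitted, np.full(500, x.mean()), atol=1e-12)

    def test_random_walk_one_step_forecast(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.standard_normal(1000))
        fit = ev.fit_arima(x, ArimaOrders(0, 1, 0))
        fitted = ev.arima_fitted(fit, x)
        dbar = np.mean(np.diff(x))
        np.testing.assert_allclose(fitted[1:], x[:-1] + dbar, atol=1e-12)

    def test_zero_residual_degenerate(self):
        x = np.linspace(0.0, 10.0, 300)  # exactly integrated deterministic trend
        fit = ev.fit_arima(x, ArimaOrders(0, 1, 0))
        fitted = ev.arima_fitted(fit, x)
        metrics = ev.error_metrics(x, fitted)
        assert metrics["MSE"] == pytest.approx(0.0, abs=1e-20)

    def test_length_mismatch_rejected(self):
        x = np.random.default_rng(4).standard_normal(400)
        fit = ev.fit_arima(x, ArimaOrders(1, 0, 0))
        with pytest.raises(ValueError, match="length"):
            ev.arima_fitted(fit, x[:-5])
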