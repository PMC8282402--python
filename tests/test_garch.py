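"""Variance recursions, quasi-MLE, and simulators for the GARCH family."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecgvol as ev
from ecgvol.garch import VolatilityOrders, VolatilityParams

SQRT_2_OVER_PI = np.sqrt(2 / np.pi)
LOG2PI = np.log(2 * np.pi)

GARCH11 = VolatilityOrders("GARCH", 1, 1)
GJR11 = VolatilityOrders("GJR", 1, 1)
EGARCH11 = VolatilityOrders("EGARCH", 1, 1)


class TestVariancePath:
    def test_garch_arithmetic(self):
        params = VolatilityParams(alpha0=0.1, alpha=[0.2], beta=[0.7])
        path = ev.variance_path([1.0, 0.0], GARCH11, params, sigma2_init=1.0)
        np.testing.assert_allclose(path, [1.0, 0.1 + 0.2 + 0.7])
        path0 = ev.variance_path([0.0, 0.0], GARCH11, params, sigma2_init=1.0)
        np.testing.assert_allclose(path0, [1.0, 0.8])

    def test_gjr_indicator_adds_gamma_on_negative_shock(self):
        params = VolatilityParams(alpha0=0.1, alpha=[0.2], beta=[0.7], gamma=[0.1])
        neg = ev.variance_path([-1.0, 0.0], GJR11, params, sigma2_init=1.0)
        pos = ev.variance_path([1.0, 0.0], GJR11, params, sigma2_init=1.0)
        assert neg[1] - pos[1] == pytest.approx(0.1, abs=1e-14)

    def test_gjr_gamma_zero_equals_garch_term_for_term(self, garch11_sample):
        y = garch11_sample
        g = VolatilityParams(alpha0=0.1, alpha=[0.2], beta=[0.7])
        gj = VolatilityParams(alpha0=0.1, alpha=[0.2], beta=[0.7], gamma=[0.0])
        np.testing.assert_array_equal(ev.variance_path(y, GARCH11, g),
                                      ev.variance_path(y, GJR11, gj))
        assert ev.volatility_loglik(y, GARCH11, g) == ev.volatility_loglik(y, GJR11, gj)

    @given(alpha0=st.floats(0.01, 1.0), a=st.floats(0.0, 0.5), b=st.floats(0.0, 0.45),
           seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_positivity_for_valid_parameters(self, alpha0, a, b, seed):
        y = np.random.default_rng(seed).standard_normal(300)
        params = VolatilityParams(alpha0=alpha0, alpha=[a], beta=[b])
        assert np.all(ev.variance_path(y, GARCH11, params) > 0)


class TestEgarchG:
    def test_zero_argument(self):
        assert ev.egarch_g(0.0, theta=0.3, lam=0.5) == pytest.approx(
            -0.5 * SQRT_2_OVER_PI, abs=1e-14)

    def test_symmetric_when_theta_zero(self):
        for z in (0.3, 1.7, 2.9):
            assert ev.egarch_g(z, 0.0, 0.4) == ev.egarch_g(-z, 0.0, 0.4)

    def test_zero_mean_under_standard_normal(self):
        z = np.random.default_rng(10).standard_normal(10**6)
        gvals = -0.1 * z + 0.2 * (np.abs(z) - SQRT_2_OVER_PI)
        se = gvals.std() / np.sqrt(z.size)
        assert abs(gvals.mean()) < 3 * se
        # spot-check the scalar function agrees with the vectorized identity
        assert ev.egarch_g(z[0], -0.1, 0.2) == pytest.approx(gvals[0], abs=1e-14)


class TestLoglik:
    def test_constant_variance_closed_form(self):
        params = VolatilityParams(alpha0=1.0, alpha=[0.0], beta=[])
        orders = VolatilityOrders("ARCH", 0, 1)
        ll = ev.volatility_loglik([0.0, 0.0, 0.0], orders, params)
        # burn-in skips t=1; two standard-normal log-densities at zero remain
        assert ll == pytest.approx(-1.0 * LOG2PI, abs=1e-12)

    def test_scaling_identity_pure_arch(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(500)
        orders = VolatilityOrders("ARCH", 0, 1)
        base = ev.volatility_loglik(y, orders, VolatilityParams(0.8, [0.3], []))
        c = 2.5
        scaled = ev.volatility_loglik(c * y, orders,
                                      VolatilityParams(c**2 * 0.8, [0.3], []))
        n_terms = y.size - 1
        assert scaled == pytest.approx(base - n_terms * np.log(c), rel=1e-12)

    def test_invalid_path_is_minus_inf(self):
        params = VolatilityParams(alpha0=-1.0, alpha=[0.2], beta=[0.7])
        assert ev.volatility_loglik([1.0, 2.0, 3.0], GARCH11, params) == -np.inf

    def test_truth_never_beats_optimum(self, garch11_sample):
        fit = ev.fit_volatility(garch11_sample, GARCH11)
        truth_ll = ev.volatility_loglik(garch11_sample, GARCH11,
                                        VolatilityParams(0.1, [0.2], [0.7]))
        assert fit.loglik >= truth_ll - 1e-8


class TestFit:
    def test_garch_recovery(self):
        sim = ev.simulate_volatility(GARCH11, VolatilityParams(0.1, [0.2], [0.7]),
                                     20000, seed=21)
        fit = ev.fit_volatility(sim["y"], GARCH11)
        d = fit.params.to_dict(GARCH11)
        assert d["alpha0"] == pytest.approx(0.1, abs=0.05)
        assert d["alpha"][0] == pytest.approx(0.2, abs=0.05)
        assert d["beta"][0] == pytest.approx(0.7, abs=0.05)

    def test_egarch_recovery_sign_and_persistence(self):
        params = VolatilityParams(alpha0=-0.01, theta=[-0.1], lam=[0.2], beta=[0.9])
        sim = ev.simulate_volatility(EGARCH11, params, 20000, seed=22)
        fit = ev.fit_volatility(sim["y"], EGARCH11)
        d = fit.params.to_dict(EGARCH11)
        assert d["theta"][0] < 0  # no sign restriction; the optimizer may cross zero
        assert d["beta"][0] == pytest.approx(0.9, abs=0.05)

    def test_iid_gaussian_moment_identity(self):
        rng = np.random.default_rng(23)
        y = rng.standard_normal(8000) * 1.3
        fit = ev.fit_volatility(y, GARCH11)
        d = fit.params.to_dict(GARCH11)
        pers = d["alpha"][0] + d["beta"][0]
        assert pers < 0.2
        assert d["alpha0"] == pytest.approx(np.var(y) * (1 - pers), rel=0.1)

    def test_deterministic(self, garch11_sample):
        a = ev.fit_volatility(garch11_sample, GARCH11)
        b = ev.fit_volatility(garch11_sample, GARCH11)
        assert a.params.to_dict(GARCH11) == b.params.to_dict(GARCH11)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ev.fit_volatility(np.zeros(20), GARCH11)


class TestSimulate:
    def test_unconditional_variance(self):
        sim = ev.simulate_volatility(GARCH11, VolatilityParams(0.1, [0.2], [0.7]),
                                     50000, seed=31)
        assert np.var(sim["y"]) == pytest.approx(1.0, abs=0.1)

    def test_degenerate_is_iid_gaussian(self):
        sim = ev.simulate_volatility(GARCH11, VolatilityParams(2.0, [0.0], [0.0]),
                                     20000, seed=32)
        np.testing.assert_allclose(sim["sigma2"], 2.0)
        assert np.var(sim["y"]) == pytest.approx(2.0, rel=0.05)
        assert ev.moments(sim["y"]).kurtosis == pytest.approx(3.0, abs=0.15)

    def test_arch_output_is_leptokurtic(self):
        params = VolatilityParams(0.7, [0.3], [0.5])
        kurts = [ev.moments(ev.simulate_volatility(GARCH11, params, 10000,
                                                   seed=s)["y"]).kurtosis
                 for s in range(10)]
        assert all(k > 3 for k in kurts)

    def test_explosive_parameters_rejected(self):
        with pytest.raises(ValueError, match="explosive"):
            ev.simulate_volatility(GARCH11, VolatilityParams(0.1, [0.6], [0.5]),
                                   100, seed=0)
        with pytest.raises(ValueError):
            ev.simulate_volatility(EGARCH11,
                                   VolatilityParams(0.0, theta=[0.1], lam=[0.2],
                                                    beta=[1.2]), 100, seed=0)

    def test_reproducible_per_seed(self):
        p = VolatilityParams(0.1, [0.2], [0.7])
        a = ev.simulate_volatility(GARCH11, p, 1000, seed=5)
        b = ev.simulate_volatility(GARCH11, p, 1000, seed=5)
        np.testing.assert_array_equal(a["y"], b["y"])


class TestRecoveryRoundTrip:
    """Simulate -> fit recovers each family within +/-0.05 on mean estimates."""

    @pytest.mark.parametrize("family", ["GARCH", "GJR", "EGARCH"])
    def test_mean_estimate_over_five_seeds(self, family):
        from ecgvol.studies import volatility_recovery_study

        out = volatility_recovery_study(family, n=20000, n_seeds=5, seed=17)
        assert out["max_abs_error"] < 0.05
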