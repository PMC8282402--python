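"""Moments, Engle ARCH-LM, Wilcoxon signed-rank, distribution comparison."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ecgvol as ev
from ecgvol.garch import VolatilityOrders, VolatilityParams


class TestMoments:
    def test_two_point_symmetric_sample(self):
        m = ev.moments([1.0, -1.0] * 10)
        assert m.kurtosis == pytest.approx(1.0, abs=1e-12)
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis(self):
        x = np.random.default_rng(1).standard_normal(10**5)
        assert ev.moments(x).kurtosis == pytest.approx(3.0, abs=0.1)

    def test_garch_sample_is_heavy_tailed(self):
        sim = ev.simulate_volatility(VolatilityOrders("GARCH", 1, 1),
                                     VolatilityParams(0.7, [0.3], [0.5]), 10000, seed=2)
        assert ev.moments(sim["y"]).kurtosis > 3

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.moments([2.0] * 50)

    @given(x=st.lists(st.floats(-100, 100), min_size=4, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_kurtosis_lower_bound(self, x):
        x = np.asarray(x)
        if np.var(x) <= 1e-12:
            return
        assert ev.moments(x).kurtosis >= 1.0 - 1e-9


class TestEngle:
    def test_chi_square_threshold_one_lag(self):
        res = ev.engle_arch_test(np.random.default_rng(3).standard_normal(200),
                                 lags=1, alpha=0.05)
        assert res.threshold == pytest.approx(3.8415, abs=5e-5)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.diagnostic import het_arch

        rng = np.random.default_rng(4)
        r = rng.standard_normal(800) * (1 + 0.5 * np.abs(rng.standard_normal(800)))
        mine = ev.engle_arch_test(r, lags=3)
        ref_stat, ref_p, _, _ = het_arch(r - r.mean(), nlags=3)
        assert mine.statistic == pytest.approx(ref_stat, rel=1e-9)
        assert mine.p_value == pytest.approx(ref_p, abs=1e-9)

    def test_scale_invariance(self):
        r = np.random.default_rng(5).standard_normal(500)
        a = ev.engle_arch_test(r, lags=2)
        b = ev.engle_arch_test(1000.0 * r, lags=2)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_power_on_arch1(self):
        orders = VolatilityOrders("ARCH", 0, 1)
        params = VolatilityParams(0.5, [0.5], [])
        decisions = [ev.engle_arch_test(
            ev.simulate_volatility(orders, params, 6000, seed=s)["y"], 1).decision
            for s in range(20)]
        assert sum(decisions) == 20

    def test_degenerate_squares_warn_not_raise(self):
        res = ev.engle_arch_test(np.array([1.0, -1.0] * 50), lags=1)
        assert res.decision == 0 and res.p_value == 1.0 and "degenerate" in res.note


class TestWilcoxon:
    def test_all_positive_differences_extreme(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(50)
        res = ev.wilcoxon_signed_rank(y + 3.0, y)
        assert res.statistic == 50 * 51 / 2
        assert res.decision == 1

    def test_scipy_cross_check(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        mine = ev.wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, correction=False, method="approx")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tie_adjustment_matches_enumerated_null_variance(self):
        """With midranked ties, (n(n+1)(2n+1) - tieadj)/24 must equal the exact
        conditional null variance of W under random sign flips."""
        d = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        n = d.size
        ranks = stats.rankdata(np.abs(d))
        ws = []
        for mask in range(2**n):
            keep = [(mask >> i) & 1 for i in range(n)]
            ws.append(float(ranks[np.array(keep, dtype=bool)].sum()))
        exact_var = np.var(ws)
        z = ev.wilcoxon_z(d + 10.0, np.full(n, 10.0))  # differences equal d
        w = ranks.sum()  # all differences positive
        implied_var = ((w - n * (n + 1) / 4.0) / z) ** 2
        assert implied_var == pytest.approx(exact_var, rel=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ev.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestDistributionCompare:
    def test_identity_has_zero_ks(self):
        x = np.random.default_rng(8).standard_normal(500)
        out = ev.distribution_compare(x, x.copy(), bins=20)
        assert out["ks_distance"] == 0.0

    def test_same_distribution_small_ks(self):
        z = np.random.default_rng(9).standard_normal(40000)
        out = ev.distribution_compare(z[:20000], z[20000:], bins=50)
        assert out["ks_distance"] < 0.02

    def test_heavy_tail_exceeds_baseline(self):
        rng = np.random.default_rng(10)
        sim = ev.simulate_volatility(VolatilityOrders("GARCH", 1, 1),
                                     VolatilityParams(0.4, [0.45], [0.5]), 20000, seed=10)
        y = sim["y"]
        gauss = rng.normal(y.mean(), y.std(), size=y.size)
        heavy = ev.distribution_compare(y, gauss, bins=50)["ks_distance"]
        z = rng.standard_normal(2 * y.size)
        baseline = ev.distribution_compare(z[: y.size], z[y.size:], bins=50)["ks_distance"]
        assert heavy > baseline

    def test_scipy_ks_cross_check(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal(800), rng.normal(0.3, 1.0, 900)
        mine = ev.distribution_compare(x, y)["ks_distance"]
        assert mine == pytest.approx(stats.ks_2samp(x, y).statistic, abs=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            ev.distribution_compare([1.0, 2.0], [3.0], bins=1)


class TestBattery:
    def test_apnea_like_segment_flags_arch(self, apnea_segments):
        seg = apnea_segments[0][0]
        report = ev.run_battery(seg)
        assert report["moments"]["kurtosis"] > 3
        assert report["engle"]["decision"] == 1

    def test_iid_control_rarely_rejects(self):
        spec = ev.ScenarioSpec(regime="homoskedastic_control", n_segments=50,
                               segment_length=6000, seed=13)
        segs, _ = ev.make_ecg_like(spec)
        rejections = sum(ev.run_battery(s)["engle"]["decision"] for s in segs)
        assert rejections / len(segs) <= 0.10

    def test_report_round_trips_through_json(self, apnea_segments):
        seg = apnea_segments[0][0]
        ref = ev.simulate_volatility(VolatilityOrders("GARCH", 1, 1),
                                     VolatilityParams(0.1, [0.2], [0.7]),
                                     seg.samples.size, seed=14)["y"]
        report = ev.run_battery(seg, garch_reference=ref)
        back = json.loads(json.dumps(report))
        assert back == report
        assert "wilcoxon" in report and "ks_distance" in report
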