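import numpy as np
import pandas as pd
import pytest

from cachetraj import (auc_series, censor_survival, compare_markers, cox_fit,
                       ipcw_auc, km_estimate, logrank_test)
from helpers import plain_concordance


class TestKaplanMeier:
    def test_uncensored_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.at(2.5) == 0.5
        assert km.median == 2.0  # first time S(t) <= 0.5

    def test_all_censored(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.at(6.5) == 1.0
        assert np.isnan(km.median)

    def test_single_event(self):
        km = km_estimate([5], [1])
        assert km.at(4.99) == 1.0
        assert km.at(5) == 0.0

    def test_step_function_monotone_from_one(self):
        rng = np.random.default_rng(0)
        km = km_estimate(rng.exponential(1, 50), rng.integers(0, 2, 50))
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestCensorSurvival:
    def test_no_censoring_is_flat_one(self):
        G = censor_survival([1, 2, 3], [1, 1, 1])
        assert G.at(2.9) == 1.0

    def test_all_censored_at_common_time(self):
        G = censor_survival([4, 4, 4], [0, 0, 0])
        assert G.at(3.9) == 1.0
        assert G.at(4) == 0.0

    def test_hand_product_limit(self):
        # censoring events at t=2 (1 of 2 at risk) -> G = 1/2 afterwards
        G = censor_survival([1, 2, 3], [1, 0, 1])
        assert G.at(1.5) == 1.0
        assert G.at(2.5) == pytest.approx(0.5)
        assert G.at(2, left=True) == 1.0  # left limit before the drop


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        chi2, df, p = logrank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(12)
        n = 200
        g = np.repeat([0, 1], n)
        t = np.concatenate([rng.exponential(1.0, n), rng.exponential(0.2, n)])
        chi2, df, p = logrank_test(t, np.ones(2 * n), g)
        assert p < 1e-3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_binary_covariate_hr_recovery(self):
        rng = np.random.default_rng(100)
        n = 1000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.5 * 3.0 ** x))
        c = rng.exponential(2.0, n)
        df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int),
                           "x": x})
        res = cox_fit(df, covariates=["x"])
        assert 2.55 <= res.hazard_ratio("x") <= 3.45
        assert res.summary.loc["x", "hr_ci_lower"] < 3.0 < res.summary.loc["x", "hr_ci_upper"]

    def test_uninformative_marker_concordance_half(self):
        rng = np.random.default_rng(7)
        n = 800
        df = pd.DataFrame({"time": rng.exponential(1.0, n),
                           "event": np.ones(n, int),
                           "x": rng.integers(0, 2, n)})
        res = cox_fit(df, covariates=["x"])
        assert abs(res.concordance - 0.5) < 0.05

    def test_perfect_ranking_concordance_one(self):
        t = np.arange(1.0, 41.0)
        df = pd.DataFrame({"time": t, "event": np.ones(40, int), "x": -t})
        res = cox_fit(df, covariates=["x"])
        assert res.concordance == 1.0

    def test_warns_on_few_events(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4, 5], "event": [1, 0, 0, 0, 0],
                           "x": [0, 1, 0, 1, 0]})
        with pytest.warns(UserWarning, match="events"):
            cox_fit(df, covariates=["x"])


class TestIpcwAuc:
    def test_reduces_to_plain_concordance_without_censoring(self):
        rng = np.random.default_rng(21)
        n = 120
        t = rng.exponential(1.0, n)
        m = rng.normal(size=n)
        auc = ipcw_auc(t, np.ones(n, int), m, 0.8)
        assert auc == pytest.approx(plain_concordance(t, np.ones(n, int), m, 0.8),
                                    abs=1e-12)

    def test_perfect_binary_separation(self):
        t = np.array([1, 2, 3, 10, 11, 12], float)
        e = np.ones(6, int)
        m = np.array([1, 1, 1, 0, 0, 0], float)
        assert ipcw_auc(t, e, m, 5.0) == 1.0

    def test_binary_tie_credit(self):
        # all-equal marker: every case/control pair gets 1/2
        t = np.array([1, 2, 10, 11], float)
        assert ipcw_auc(t, np.ones(4, int), np.ones(4), 5.0) == 0.5

    def test_independent_marker_unbiased_at_half(self):
        rng = np.random.default_rng(5)
        n = 1000
        vals = []
        for _ in range(20):
            t = rng.exponential(1.0, n)
            c = rng.exponential(2.0, n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            m = rng.integers(0, 2, n)
            vals.append(ipcw_auc(time, event, m, float(np.median(time))))
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_no_cases_undefined(self):
        assert np.isnan(ipcw_auc([10, 11], [1, 1], [0, 1], 5.0))

    def test_matches_scikit_survival_on_continuous_marker(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv
        rng = np.random.default_rng(42)
        n = 300
        risk = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * risk))
        c = rng.exponential(1.5, n)
        time = np.minimum(t, c)
        event = t <= c
        y = Surv.from_arrays(event, time)
        horizons = np.quantile(time, [0.25, 0.5, 0.75])
        theirs, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, risk, horizons)
        ours = [ipcw_auc(time, event.astype(int), risk, h) for h in horizons]
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestAucSeries:
    @staticmethod
    def _data(n=300, seed=3):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, n)
        t = rng.exponential(400 / (1 + m), n)
        c = rng.exponential(900, n)
        return np.minimum(t, c), (t <= c).astype(int), m

    def test_horizon_grid_contract(self):
        time, event, m = self._data()
        s = auc_series(time, event, m, median_os_days=200.0, n_boot=0)
        assert len(s.horizons_months) == int(200.0 // (365.25 / 12))
        assert np.all(np.diff(s.horizons_months) > 0)

    def test_bootstrap_deterministic_given_seed(self):
        time, event, m = self._data()
        a = auc_series(time, event, m, 200.0, n_boot=25, seed=9)
        b = auc_series(time, event, m, 200.0, n_boot=25, seed=9)
        np.testing.assert_array_equal(a.ci_lower, b.ci_lower)
        np.testing.assert_array_equal(a.ci_upper, b.ci_upper)
        assert np.all((a.ci_lower <= a.auc) & (a.auc <= a.ci_upper))

    def test_informative_marker_above_half(self):
        time, event, m = self._data()
        s = auc_series(time, event, m, 200.0, n_boot=0)
        assert np.nanmean(s.auc) > 0.55


class TestCompareMarkers:
    def test_identical_markers_null(self):
        time, event, m = TestAucSeries._data()
        diff, p = compare_markers(time, event, m, m, 150.0, n_boot=50, seed=1)
        assert diff == 0.0
        assert p == 1.0

    def test_dominant_marker_detected(self):
        rng = np.random.default_rng(17)
        n = 400
        m = rng.integers(0, 2, n)
        noise = rng.integers(0, 2, n)
        t = rng.exponential(300 / (1 + 4 * m), n)
        diff, p = compare_markers(t, np.ones(n, int), m, noise, 150.0,
                                  n_boot=200, seed=2)
        assert diff > 0.1
        assert p < 0.05
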