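import numpy as np
import pandas as pd
import pytest

from petlymph import (
    CoxPH,
    SurvivalSample,
    combined_strata,
    km_estimate,
    logrank_test,
    roc_best_cutoff,
)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # (5, event), (10, censored), (15, event):
        # S(5) = 2/3; at 15 one of one at risk fails -> S(15) = 0; median 15
        curve = km_estimate(SurvivalSample([5, 10, 15], [1, 0, 1]))
        assert curve.survival_at(5) == pytest.approx(2 / 3)
        assert curve.survival_at(15) == pytest.approx(0.0)
        assert curve.median_months == 15

    def test_no_events_gives_flat_curve_and_no_median(self):
        curve = km_estimate(SurvivalSample([3, 7, 11], [0, 0, 0]))
        assert len(curve.event_times) == 0
        assert np.all(curve.survival_at([1, 5, 20]) == 1.0)
        assert curve.median_months is None

    def test_all_events_steps_by_one_over_n(self):
        curve = km_estimate(SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(curve.survival_probabilities, [0.75, 0.5, 0.25, 0.0])

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, 200)
        curve = km_estimate(SurvivalSample(t, np.ones(200, int)))
        for q in (5.0, 10.0, 20.0):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_probabilities_nonincreasing_from_one(self, rng):
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        e[0] = 1
        curve = km_estimate(SurvivalSample(t, e))
        assert curve.survival_probabilities[0] <= 1.0
        assert np.all(np.diff(curve.survival_probabilities) <= 1e-12)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        g = SurvivalSample([2, 4, 6, 8], [1, 1, 0, 1])
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_reference(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(5):
            n = 60
            t = (rng.exponential(15, n) + 0.1).round(1)  # rounding forces ties
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            chi2, p = logrank_test(
                SurvivalSample(t[g == 0], e[g == 0]), SurvivalSample(t[g == 1], e[g == 1])
            )
            ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
            assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_order_preserving_relabeling_invariance(self, rng):
        t = rng.exponential(15, 50)
        e = rng.integers(0, 2, 50)
        e[:5] = 1
        g = rng.integers(0, 2, 50)
        a = logrank_test(SurvivalSample(t[g == 0], e[g == 0]), SurvivalSample(t[g == 1], e[g == 1]))
        t2 = np.log1p(t)  # strictly monotone transform of time
        b = logrank_test(SurvivalSample(t2[g == 0], e[g == 0]), SurvivalSample(t2[g == 1], e[g == 1]))
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_empty_group_rejected(self):
        g = SurvivalSample([1, 2], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(g, SurvivalSample([], []))


class TestCoxPH:
    def test_two_group_hazard_ratio_recovery(self, rng):
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(20 * np.exp(-np.log(2.3) * x))
        c = rng.exponential(60, n)
        e = (t <= c).astype(int)
        fit = CoxPH(SurvivalSample(np.minimum(t, c), e), x[:, None], names=["grp"]).fit()
        lo, hi = fit.conf_int()[0]
        assert lo < 2.3 < hi
        assert fit.converged

    def test_null_covariate_recovers_unit_hazard_ratio(self, rng):
        n = 800
        x = rng.normal(size=n)
        t = rng.exponential(20, n)
        fit = CoxPH(SurvivalSample(t, np.ones(n, int)), x[:, None]).fit()
        assert fit.hazard_ratios[0] == pytest.approx(1.0, abs=0.15)

    def test_matches_lifelines_on_small_data(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        x = rng.normal(size=(n, 2))
        t = (rng.exponential(20 * np.exp(-0.5 * x[:, 0])) + 0.1).round(1)
        e = rng.integers(0, 2, n)
        e[:10] = 1
        fit = CoxPH(SurvivalSample(t, e), x).fit()
        df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-9})
        np.testing.assert_allclose(fit.params, ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.bse, ref.standard_errors_.to_numpy(), atol=1e-5)

    def test_breslow_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 100
        x = rng.normal(size=(n, 2))
        t = (rng.exponential(10 * np.exp(-0.4 * x[:, 0])) + 0.1).round(1)
        e = rng.integers(0, 2, n)
        e[:10] = 1
        fit = CoxPH(SurvivalSample(t, e), x).fit(ties="breslow")
        ref = sm.PHReg(t, x, status=e, ties="breslow").fit()
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-8)

    def test_perfect_separation_flagged(self):
        # the covariate perfectly orders the event times: monotone likelihood
        t = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        e = np.ones(8, int)
        x = np.r_[np.ones(4), np.zeros(4)]
        fit = CoxPH(SurvivalSample(t, e), x[:, None]).fit()
        assert any("separation" in f or "monotone" in f for f in fit.flags)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            CoxPH(SurvivalSample([1, 2, 3], [1, 1, 1]), np.ones((3, 1)))

    def test_summary_table_shape(self, rng):
        n = 60
        x = rng.normal(size=(n, 2))
        fit = CoxPH(SurvivalSample(rng.exponential(5, n), np.ones(n, int)), x, names=["a", "b"]).fit()
        tab = fit.summary()
        assert list(tab.index) == ["a", "b"]
        assert {"HR", "p", "coef"} <= set(tab.columns)
        ci = fit.conf_int()
        assert np.all(ci[:, 0] <= fit.hazard_ratios) and np.all(fit.hazard_ratios <= ci[:, 1])


class TestRocCutoff:
    def test_perfect_separation(self):
        x = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        cut = roc_best_cutoff(x, y)
        assert cut.youden_j == pytest.approx(1.0)
        assert cut.auc == pytest.approx(1.0)
        assert 3 < cut.threshold < 10

    def test_six_point_hand_example_matches_exhaustive_search(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 1, 0, 1, 1, 1])
        cut = roc_best_cutoff(x, y)
        # brute force over every possible cut
        best_j, best_thr = -np.inf, None
        for thr in np.arange(0.5, 7.0, 0.5):
            sens = ((x > thr) & (y == 1)).sum() / 4
            spec = ((x <= thr) & (y == 0)).sum() / 2
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_thr = sens + spec - 1, thr
        assert cut.youden_j == pytest.approx(best_j)
        assert abs(cut.threshold - best_thr) <= 0.5  # same inter-value gap

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(5):
            x = rng.normal(size=60).round(1)  # ties included
            y = rng.integers(0, 2, 60)
            if y.sum() in (0, 60):
                continue
            assert roc_best_cutoff(x, y).auc == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    def test_uninformative_feature_auc_near_half(self, rng):
        x = rng.normal(size=4000)
        y = rng.integers(0, 2, 4000)
        assert roc_best_cutoff(x, y).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_best_cutoff(np.array([1.0, 2.0]), np.array([1, 1]))


class TestCombinedStrata:
    @pytest.mark.parametrize(
        "mtv,resp,expected",
        [
            (100, "complete", "lowMTV_CMR"),
            (100, "not_complete", "lowMTV_nonCMR"),
            (900, "complete", "highMTV_CMR"),
            (900, "not_complete", "highMTV_nonCMR"),
            (500, "complete", "lowMTV_CMR"),  # exactly at cutoff -> low group
        ],
    )
    def test_assignment(self, mtv, resp, expected):
        assert combined_strata(mtv, 500, resp) == expected

    def test_missing_response_excluded(self):
        assert combined_strata(100, 500, None) is None
        assert combined_strata(100, 500, float("nan")) is None
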