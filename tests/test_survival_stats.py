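"""Kaplan-Meier, log-rank, Cox, median split, chi-square and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter

from immunoscape.survival_stats import (bh_fdr, categorical_association,
                                        cox_ph, km_curve, logrank_test,
                                        median_split, multigroup_logrank)

from conftest import exp_surv_data


class TestKMCurve:
    def test_product_limit_by_hand(self):
        km = km_curve([1, 2], [1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_all_censored_flat_at_one(self):
        km = km_curve([3, 5, 9], [0, 0, 0])
        assert (km.survival == 1).all()

    def test_event_before_censoring_at_tie(self):
        # censored subject at t=2 still in the risk set for the t=2 event
        km = km_curve([1, 2, 2, 3], [1, 1, 0, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.0])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 50)
        km = km_curve(t, np.ones(50))
        for i, ti in enumerate(km.times):
            assert km.survival[i] == pytest.approx((t > ti).mean())

    def test_matches_lifelines(self, rng):
        x, t, e = exp_surv_data(rng, 80)
        km = km_curve(t, e)
        lf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx(
                lf.survival_function_at_times(ti).iloc[0], abs=1e-10)


class TestLogrank:
    def test_hand_computed_example(self):
        chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(49 / 17, abs=1e-3)

    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 0, 1, 1, 0, 1]
        g = ["A"] * 3 + ["B"] * 3
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self, rng):
        x, t, e = exp_surv_data(rng, 60, log_hr=0.5)
        c1, _ = logrank_test(t, e, x)
        c2, _ = logrank_test(t, e, 1 - x)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_monotone_time_transform_invariance(self, rng):
        x, t, e = exp_surv_data(rng, 60, log_hr=0.5)
        c1, _ = logrank_test(t, e, x)
        c2, _ = logrank_test(np.log1p(t), e, x)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], ["A", "A"])
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], ["A", "B"])


class TestCox:
    def test_score_test_equals_logrank(self, rng):
        """Cox score statistic at beta=0 matches the log-rank chi-square."""
        x, t, e = exp_surv_data(rng, 150, log_hr=0.6)
        fit = cox_ph(x.reshape(-1, 1), t, e)
        chi2, _ = logrank_test(t, e, x)
        assert fit.score_chi2 == pytest.approx(chi2, abs=1e-6)

    def test_matches_lifelines_efron(self, rng):
        x, t, e = exp_surv_data(rng, 120, log_hr=0.7)
        z = rng.standard_normal(120)
        df = pd.DataFrame({"x": x, "z": z, "t": t, "e": e})
        mine = cox_ph(df[["x", "z"]], t, e)
        lf = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        for f in mine.fits:
            assert f.coef == pytest.approx(lf.params_[f.covariate], abs=1e-6)
            assert f.log_hr_se == pytest.approx(
                lf.standard_errors_[f.covariate], abs=1e-6)

    def test_loglik_trace_monotone(self, rng):
        x, t, e = exp_surv_data(rng, 100, log_hr=1.0)
        fit = cox_ph(x.reshape(-1, 1), t, e)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_planted_hr_recovered(self, rng):
        """Mean estimated log-HR over replicates is close to the truth."""
        est = []
        for _ in range(40):
            x, t, e = exp_surv_data(rng, 400, log_hr=np.log(2))
            est.append(cox_ph(x.reshape(-1, 1), t, e).fits[0].coef)
        assert abs(np.mean(est) - np.log(2)) < 0.07

    def test_null_coverage(self, rng):
        """95% CI covers HR=1 about 95% of the time for a null covariate."""
        covered = 0
        reps = 200
        for _ in range(reps):
            x, t, e = exp_surv_data(rng, 120, log_hr=0.0)
            f = cox_ph(x.reshape(-1, 1), t, e).fits[0]
            covered += f.ci95[0] <= 1.0 <= f.ci95[1]
        assert covered / reps == pytest.approx(0.95, abs=0.045)

    def test_errors(self, rng):
        x, t, e = exp_surv_data(rng, 50)
        with pytest.raises(ValueError, match="constant covariate"):
            cox_ph(np.ones((50, 1)), t, e)
        with pytest.raises(ValueError, match="no events"):
            cox_ph(x.reshape(-1, 1), t, np.zeros(50))


class TestMedianSplit:
    @pytest.mark.parametrize("values,lows", [
        ([1, 2, 3, 4], 2),            # half/half
        ([1, 2, 2, 3], 3),            # ties at the median go low
    ])
    def test_split(self, values, lows):
        labels = median_split(values)
        assert (labels == "low").sum() == lows

    def test_degenerate_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([5, 5, 5])


class TestCategoricalAssociation:
    def test_perfect_association(self):
        a = ["x"] * 10 + ["y"] * 10
        chi2, df, p, _ = categorical_association(a, a)
        assert chi2 == pytest.approx(20.0)
        assert df == 1
        assert p < 1e-4

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            a = rng.integers(0, 2, 60)
            b = rng.integers(0, 2, 60)
            ps.append(categorical_association(a, b)[2])
        assert np.mean(ps) == pytest.approx(0.5, abs=0.12)

    def test_degenerate_table(self):
        with pytest.raises(ValueError, match="degenerate"):
            categorical_association(["x"] * 4, ["a", "a", "b", "b"])


class TestBHFdr:
    def test_brute_force_example(self):
        # step-up by hand: q_i = min over j>=i of p_(j) * m / j
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_random(self, rng):
        p = rng.random(50)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        brute = np.empty(m)
        brute[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), brute, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_q_at_least_p(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)

    def test_invalid_p_is_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestMultigroupLogrank:
    def test_two_group_case_matches_binary(self, rng):
        x, t, e = exp_surv_data(rng, 80, log_hr=0.8)
        chi2b, _ = logrank_test(t, e, x)
        chi2m, df, _ = multigroup_logrank(t, e, x)
        assert df == 1
        assert chi2m == pytest.approx(chi2b, rel=1e-9)
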