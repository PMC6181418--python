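"""Survival engine: KM closed forms, log-rank vs brute force and lifelines,
Cox vs brute force / lifelines / frozen R values, rank-sum comparisons."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from tilscore import (SimulationConfig, compare_density_groups, cox_fit,
                      generate_cohort, km_estimate, logrank_test,
                      logrank_trend)
from tilscore.errors import ConvergenceError, DataError
from oracles import (brute_cox_1cov, brute_km, brute_logrank_2group,
                     brute_ranksum_exact_p)


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        times = [1.0, 2.0, 3.0]
        curve = km_estimate(times, [1, 1, 1])
        assert list(curve.times) == times
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_hand_computed_censored_example(self):
        # events at 1 and 3, censored at 2: S = 2/3 on [1,3), 0 after
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert list(curve.times) == [1.0, 3.0]
        assert curve.survival == pytest.approx([2 / 3, 0.0])
        assert curve.survival_at(2.5) == pytest.approx(2 / 3)
        assert curve.survival_at(0.5) == 1.0

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_matches_brute_force_with_random_censoring(self, rng):
        times = np.ceil(rng.exponential(10, 60))
        events = rng.integers(0, 2, 60)
        events[0] = 1
        curve = km_estimate(times, events)
        bt, bs = brute_km(times, events)
        assert list(curve.times) == bt
        assert curve.survival == pytest.approx(bs)

    def test_greenwood_se_zero_before_events_positive_after(self, rng):
        times = np.r_[rng.uniform(1, 30, 40)]
        events = np.r_[np.ones(20, int), np.zeros(20, int)]
        curve = km_estimate(times, events)
        interior = curve.survival > 0
        assert (curve.greenwood_se[interior] > 0).all()

    def test_bad_inputs(self):
        with pytest.raises(DataError):
            km_estimate([], [])
        with pytest.raises(DataError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogRank:
    def test_identical_groups_give_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        res = logrank_test(times, events, ["a"] * 3 + ["b"] * 3)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_oracle_with_tie(self):
        # implementer-constructed n=8 set including a tied event time
        times = [2.0, 3.0, 3.0, 5.0, 1.0, 4.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 1, 1, 0]
        group2 = [False] * 4 + [True] * 4
        res = logrank_test(times, events, group2)
        assert res.chi_square == pytest.approx(
            brute_logrank_2group(times, events, group2), abs=1e-12)

    def test_df_is_k_minus_one(self, rng):
        times = rng.uniform(1, 20, 50)
        events = rng.integers(0, 2, 50)
        events[:5] = 1
        res = logrank_test(times, events, rng.integers(0, 5, 50))
        assert res.df == 4

    def test_relabeling_invariance(self, rng):
        times = rng.uniform(1, 20, 40)
        events = rng.integers(0, 2, 40)
        events[0] = 1
        labels = rng.integers(0, 2, 40)
        a = logrank_test(times, events, labels)
        b = logrank_test(times, events, 1 - labels)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-10)
        assert a.df == b.df

    def test_observed_and_expected_totals_agree(self, rng):
        times = rng.uniform(1, 20, 60)
        events = rng.integers(0, 2, 60)
        events[0] = 1
        res = logrank_test(times, events, rng.integers(0, 3, 60))
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_matches_lifelines_k_group(self, rng):
        times = np.ceil(rng.uniform(1, 20, 80))
        events = rng.integers(0, 2, 80)
        events[0] = 1
        groups = rng.integers(0, 3, 80)
        res = logrank_test(times, events, groups)
        ll = multivariate_logrank_test(times, groups, events)
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)

    def test_error_cases(self):
        with pytest.raises(DataError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])
        with pytest.raises(DataError):
            logrank_test([1.0, 2.0], [0, 0], ["a", "b"])


class TestTrend:
    def test_two_groups_reduce_to_ordinary_logrank(self, rng):
        times = np.ceil(rng.uniform(1, 15, 50))
        events = rng.integers(0, 2, 50)
        events[0] = 1
        groups = rng.integers(0, 2, 50)
        trend = logrank_trend(times, events, groups)
        ordinary = logrank_test(times, events, groups)
        assert trend.chi_square == pytest.approx(ordinary.chi_square,
                                                 rel=1e-9)
        assert trend.df == 1

    def test_identical_groups_zero(self):
        times = [1.0, 2.0, 3.0] * 3
        events = [1, 1, 0] * 3
        grades = [0] * 3 + [1] * 3 + [2] * 3
        assert logrank_trend(times, events, grades).chi_square == pytest.approx(
            0.0, abs=1e-12)

    def test_monotone_hazard_favors_trend_over_heterogeneity(self):
        rng = np.random.default_rng(3)
        n = 500
        grade = rng.integers(0, 5, n)
        times = rng.exponential(np.exp(0.5 * grade) * 10)
        times = np.maximum(times, 0.01)
        events = (times < 40).astype(int)
        times = np.minimum(times, 40.0)
        trend = logrank_trend(times, events, grade)
        hetero = logrank_test(times, events, grade)
        assert trend.chi_square > hetero.chi_square / hetero.df


class TestCox:
    def test_single_covariate_matches_brute_force_grid(self):
        rng = np.random.default_rng(12)
        x = np.r_[np.zeros(5), np.ones(5)]
        times = rng.exponential(np.where(x == 1, 4.0, 10.0))  # no ties
        events = np.ones(10, int)
        model = cox_fit(pd.DataFrame({"x": x}), times, events)
        brute = brute_cox_1cov(times, events, x)
        assert model.log_hr[0] == pytest.approx(brute, abs=1e-4)

    def test_frozen_r_coxph_values_both_tie_methods(self):
        # data regenerated from the same seed; reference values from
        # survival::coxph(Surv(t,e)~x1+x2, ties=...)
        rng = np.random.default_rng(5)
        n = 40
        x1 = rng.integers(0, 2, n)
        x2 = rng.normal(0, 1, n).round(2)
        t = np.ceil(rng.exponential(10, n))
        e = rng.integers(0, 2, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        efron = cox_fit(X, t, e, ties="efron")
        assert efron.log_hr == pytest.approx([0.3337927, -0.02401751],
                                             abs=1e-6)
        assert efron.se == pytest.approx([0.4790282, 0.276803], abs=1e-6)
        breslow = cox_fit(X, t, e, ties="breslow")
        assert breslow.log_hr == pytest.approx([0.3439312, -0.01717634],
                                               abs=1e-6)
        assert breslow.se == pytest.approx([0.4793759, 0.2764446], abs=1e-6)

    def test_constant_covariate_rejected_by_name(self, default_cohort):
        X = pd.DataFrame({"flat": np.ones(len(default_cohort))})
        with pytest.raises(DataError, match="flat"):
            cox_fit(X, default_cohort.os_months, default_cohort.os_event)

    def test_time_unit_invariance(self, default_cohort):
        X = pd.DataFrame({"lvi": default_cohort.lvi})
        months = cox_fit(X, default_cohort.os_months, default_cohort.os_event)
        years = cox_fit(X, default_cohort.os_months / 12.0,
                        default_cohort.os_event)
        assert months.hr[0] == pytest.approx(years.hr[0], rel=1e-8)

    def test_ci_is_wald_exponentiated(self, default_cohort):
        X = pd.DataFrame({"lvi": default_cohort.lvi})
        m = cox_fit(X, default_cohort.os_months, default_cohort.os_event)
        z = 1.959963984540054
        assert m.ci_lower[0] == pytest.approx(
            np.exp(m.log_hr[0] - z * m.se[0]))
        assert m.ci_upper[0] == pytest.approx(
            np.exp(m.log_hr[0] + z * m.se[0]))

    def test_perfect_separation_flagged(self):
        # covariate=1 patients all fail first: monotone likelihood
        times = np.r_[np.arange(1, 11), np.arange(11, 21)].astype(float)
        events = np.r_[np.ones(10, int), np.zeros(10, int)]
        x = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ConvergenceError):
            cox_fit(pd.DataFrame({"x": x}), times, events)

    def test_opposite_pair_shrinks_toward_null(self, default_cohort):
        X = pd.DataFrame({"lvi": default_cohort.lvi})
        t, e = default_cohort.os_months, default_cohort.os_event
        base = cox_fit(X, t, e)
        # duplicate the cohort with the covariate flipped: effect cancels
        X2 = pd.concat([X, 1 - X], ignore_index=True)
        t2 = pd.concat([t, t], ignore_index=True)
        e2 = pd.concat([e, e], ignore_index=True)
        doubled = cox_fit(X2, t2, e2)
        assert abs(doubled.log_hr[0]) < abs(base.log_hr[0])

    def test_recovers_true_hr_large_n(self):
        # cohort carrying a single density effect: HR 0.35 on high CD8_IM
        cfg = SimulationConfig(
            seed=7, n_patients=2000,
            true_log_hr={"cd3_ct": 0.0, "cd3_im": 0.0, "cd8_ct": 0.0,
                         "cd8_im": float(np.log(0.35))})
        c = generate_cohort(cfg)
        X = pd.DataFrame({"high": (c.cd8_im > 70).astype(int)})
        for cov in ["organ_confined", "lvi", "margin", "intravesical",
                    "chemo"]:
            X[cov] = c[cov]
        m = cox_fit(X, c.os_months, c.os_event)
        assert 0.30 <= m.hr[0] <= 0.41  # truth 0.35, ±3 SE


class TestCompareDensityGroups:
    def test_identical_samples_maximal_p(self):
        d = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = [0, 0, 0, 1, 1, 1]
        _, p = compare_density_groups(d, labels)
        assert p > 0.99

    def test_exact_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        stat, p = compare_density_groups(a + b, [0, 0, 0, 1, 1, 1])
        exact = brute_ranksum_exact_p(a, b)
        assert p == pytest.approx(exact, abs=1e-12)

    def test_power_against_shift(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = np.exp(rng.normal(4.0, 1.0, 30))
            b = np.exp(rng.normal(5.0, 1.0, 30))  # +1 log-density shift
            _, p = compare_density_groups(
                np.r_[a, b], np.r_[np.zeros(30), np.ones(30)])
            hits += p < 0.05
        assert hits / reps >= 0.8

    def test_welch_alternative_and_errors(self):
        d = [1.0, 2.0, 10.0, 12.0]
        _, p = compare_density_groups(d, [0, 0, 1, 1], method="welch")
        assert 0 < p <= 1
        with pytest.raises(DataError):
            compare_density_groups([1.0, 2.0], [0, 0])
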