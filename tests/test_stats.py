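"""Evaluation-battery tests with independent brute-force oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glytrial as gt
from glytrial.protocol import BGCategory
from glytrial.stats import (
    ConvergenceError,
    DegenerateDataError,
    cox_two_group,
    cv_percent,
    icc_oneway,
    km_fit,
    percent_in_target,
    recurrence_after_first,
    summarize_events,
    time_to_target,
    two_proportion_test,
    variability_stats,
    zinb_compare,
    zinb_fit,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        fit = km_fit([2, 4, 6], [1, 1, 1])
        lookup = dict(zip(fit.times, fit.survival))
        assert lookup[2] == pytest.approx(2 / 3)
        assert lookup[4] == pytest.approx(1 / 3)
        assert lookup[6] == pytest.approx(0.0)
        assert fit.median == 4

    def test_all_censored_has_undefined_median(self):
        fit = km_fit([3, 5, 9], [0, 0, 0])
        assert np.allclose(fit.survival, 1.0)
        assert fit.median is None

    def test_median_is_first_time_survival_drops_to_half(self):
        fit = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert fit.median == 2  # S(2) = 0.5 exactly


class TestCox:
    def test_identical_groups_hr_one(self):
        times = [2, 3, 5, 7, 11, 13] * 2
        events = [1, 1, 0, 1, 1, 0] * 2
        group = [0] * 6 + [1] * 6
        fit = cox_two_group(times, events, group)
        assert fit.hr == pytest.approx(1.0, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cox_two_group([1, 2, 3], [1, 1, 1], [0, 0, 0])

    def test_group_without_events_rejected(self):
        with pytest.raises(ValueError):
            cox_two_group([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])

    def test_monotone_likelihood_signalled(self):
        # complete separation: all group-1 events long before any group-0
        times = [1, 2, 3, 4, 100, 200, 300, 400]
        events = [1] * 8
        group = [1, 1, 1, 1, 0, 0, 0, 0]
        with pytest.raises(ConvergenceError):
            cox_two_group(times, events, group)

    def test_reference_orientation(self):
        rng = np.random.default_rng(4)
        t0 = rng.exponential(1.0, 200)
        t1 = rng.exponential(0.5, 200)
        times = np.concatenate([t0, t1])
        events = np.ones(400)
        group = np.array(["static"] * 200 + ["dynamic"] * 200)
        fit = cox_two_group(times, events, group, reference="static")
        assert fit.group == "dynamic" and fit.reference == "static"
        assert fit.hr > 1  # dynamic reaches the event faster


class TestCV:
    def test_constant_series_zero(self):
        assert cv_percent([120, 120, 120]) == 0.0

    def test_worked_example(self):
        assert cv_percent([100, 150, 200]) == pytest.approx(100 * 50 / 150)

    @given(
        values=st.lists(
            st.floats(min_value=50, max_value=400), min_size=2, max_size=20
        ),
        k=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, values, k):
        assert cv_percent([k * v for v in values]) == pytest.approx(
            cv_percent(values), rel=1e-9
        )

    def test_requires_two_values_and_positive_mean(self):
        with pytest.raises(ValueError):
            cv_percent([100])
        with pytest.raises(ValueError):
            cv_percent([-1, 1])


class TestICC:
    def test_perfect_separation_gives_one(self):
        assert icc_oneway([[10, 10, 10], [20, 20, 20], [30, 30, 30]]) == 1.0

    def test_iid_groups_give_near_zero(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(100, 15, 20).tolist() for _ in range(200)]
        assert icc_oneway(groups) < 0.05

    def test_matches_hand_anova_oracle(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 12.0]]
        # independent oracle: explicit sums of squares, balanced so k0 = n
        allv = [x for g in groups for x in g]
        grand = sum(allv) / len(allv)
        means = [sum(g) / len(g) for g in groups]
        ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
        ssw = sum((x - m) ** 2 for g, m in zip(groups, means) for x in g)
        msb = ssb / (len(groups) - 1)
        msw = ssw / (len(allv) - len(groups))
        expected = (msb - msw) / (msb + (3 - 1) * msw)
        assert icc_oneway(groups) == pytest.approx(expected, rel=1e-12)

    def test_negative_estimates_truncated_to_zero(self):
        # within-variance dwarfs between-variance -> raw estimator negative
        groups = [[0.0, 100.0], [49.0, 51.0], [0.0, 100.0], [50.0, 50.0]]
        assert icc_oneway(groups) == 0.0

    def test_requires_replication(self):
        with pytest.raises(ValueError):
            icc_oneway([[1], [2]])


class TestRecurrence:
    def _dataset(self, series):
        from glytrial.records import BGRecord, TrialDataset

        records, profiles, end = {}, {}, {}
        for pid, bgs in series.items():
            recs = []
            for i, bg in enumerate(bgs):
                cat = gt.classify_bg(bg, gt.Frailty.VIGOROUS)
                recs.append(
                    BGRecord(pid, 2.0 * i, bg, cat, 1.0, 1.0, 0.0, 2.0, 2.0)
                )
            recs[-1].actual_gap = math.nan
            records[pid] = recs
            profiles[pid] = gt.Frailty.VIGOROUS
            end[pid] = recs[-1].time
        return TrialDataset("static", records, profiles, end)

    def test_single_episode_then_clean_gives_zero(self):
        ds = self._dataset({"a": [60] + [150] * 9})
        stats = recurrence_after_first(ds)
        assert stats.per_patient == {"a": 0.0}

    def test_one_in_four_after_first(self):
        ds = self._dataset({"a": [150, 60, 150, 60, 150, 150]})
        stats = recurrence_after_first(ds)
        assert stats.per_patient["a"] == pytest.approx(25.0)

    def test_matches_naive_recount(self, small_trial):
        stats = recurrence_after_first(small_trial)
        for pid, pct_val in stats.per_patient.items():
            cats = [r.category for r in small_trial.records[pid]]
            hypo = [c in gt.HYPO_CATEGORIES for c in cats]
            first = hypo.index(True)
            later = hypo[first + 1 :]
            assert pct_val == pytest.approx(100.0 * sum(later) / len(later))

    def test_patient_without_followup_not_qualifying(self):
        ds = self._dataset({"a": [150, 150, 60]})
        assert recurrence_after_first(ds).n == 0


class TestZinb:
    @staticmethod
    def _simulate(rng, n=2000, mu=0.07, k=1.5, pi=0.3, lo=30, hi=80):
        expo = rng.uniform(lo, hi, n)
        lam = rng.gamma(k, mu * expo / k)
        y = rng.poisson(lam)
        y[rng.random(n) < pi] = 0
        return y, expo

    def test_zero_inflation_likelihood_nests_plain_nb(self):
        """At pi -> 0 the ZINB likelihood equals the plain NB likelihood."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        y, expo = self._simulate(rng, n=300, pi=0.0)
        exog = np.ones((len(y), 1))
        zinb = sm.ZeroInflatedNegativeBinomialP(
            y, exog, exog_infl=exog, exposure=expo, p=2
        )
        nb = sm.NegativeBinomialP(y, exog, exposure=expo, p=2)
        params = np.array([0.2, 0.6])  # arbitrary (const, alpha)
        ll_nb = nb.loglike(params)
        ll_zinb = zinb.loglike(np.concatenate([[-40.0], params]))  # pi ~ 0
        assert ll_zinb == pytest.approx(ll_nb, abs=1e-6)

    def test_all_zero_counts_signalled(self):
        with pytest.raises(DegenerateDataError):
            zinb_fit([0] * 50, [10.0] * 50)

    def test_group_comparison_detects_rate_ratio(self):
        rng = np.random.default_rng(15)
        ya, ea = self._simulate(rng, n=600, mu=0.10)
        yb, eb = self._simulate(rng, n=600, mu=0.05)
        cmp_ = zinb_compare(ya, ea, yb, eb)
        assert cmp_.rate_ratio == pytest.approx(0.5, rel=0.2)
        assert cmp_.p < 0.001

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            zinb_fit([1, 2, 0], [5, 5, 5])


class TestProportions:
    def test_identical_proportions_not_significant(self):
        res = two_proportion_test(50, 100, 50, 100)
        assert res.p > 0.99
        assert res.pct_a == res.pct_b == 50.0

    def test_fisher_used_for_sparse_tables(self):
        res = two_proportion_test(1, 10, 8, 10)
        assert res.method == "fisher"


class TestSummaries:
    def test_counts_match_naive_recount(self, small_trial):
        summary = summarize_events(small_trial)
        recount = {c: 0 for c in BGCategory}
        for rec in small_trial.all_records():
            recount[rec.category] += 1
        assert summary.category_counts == recount
        assert summary.n_measurements == small_trial.n_records

    def test_category_counts_conserve_total(self, small_trial):
        summary = summarize_events(small_trial)
        assert sum(summary.category_counts.values()) == summary.n_measurements

    def test_all_in_target_log_has_no_adverse_rates(self):
        from glytrial.records import BGRecord, TrialDataset

        recs = [
            BGRecord("a", 2.0 * i, 150.0, BGCategory.IN_TARGET, 1, 1, 0, 2, 2)
            for i in range(10)
        ]
        recs[-1].actual_gap = math.nan
        ds = TrialDataset(
            "static", {"a": recs}, {"a": gt.Frailty.VIGOROUS}, {"a": recs[-1].time}
        )
        s = summarize_events(ds)
        assert s.mild_episodes == s.marked_episodes == 0
        assert s.post_target_hyper == 0
        pit = percent_in_target(ds)
        assert pit["overall_pct"] == 100.0

    def test_percent_in_target_worked_example(self):
        from glytrial.records import BGRecord, TrialDataset

        bgs = [300, 300, 150, 150, 150, 150, 300, 300, 300, 300]
        recs = [
            BGRecord(
                "a", 2.0 * i, float(bg),
                gt.classify_bg(bg, gt.Frailty.VIGOROUS), 1, 1, 0, 2, 2
            )
            for i, bg in enumerate(bgs)
        ]
        recs[-1].actual_gap = math.nan
        ds = TrialDataset(
            "static", {"a": recs}, {"a": gt.Frailty.VIGOROUS}, {"a": recs[-1].time}
        )
        assert percent_in_target(ds)["overall_pct"] == 40.0

    def test_time_to_target_first_crossing(self, small_trial):
        ttt = time_to_target(small_trial).set_index("patient_id")
        for pid, recs in small_trial.records.items():
            crossing = next(
                (r.time for r in recs if r.category is BGCategory.IN_TARGET), None
            )
            if crossing is None:
                assert ttt.loc[pid, "event"] == 0
                assert ttt.loc[pid, "time_h"] == recs[-1].time
            else:
                assert ttt.loc[pid, "event"] == 1
                assert ttt.loc[pid, "time_h"] == crossing

    def test_variability_stats_consistent_with_cv(self, small_trial):
        vs = variability_stats(small_trial)
        for pid, cv_val in vs.cv_per_patient.items():
            recs = small_trial.records[pid]
            idx = next(
                i for i, r in enumerate(recs) if r.category is BGCategory.IN_TARGET
            )
            assert cv_val == pytest.approx(cv_percent([r.bg for r in recs[idx:]]))
        assert 0.0 <= vs.icc <= 1.0


class TestCompareArms:
    def test_identical_arms_null_contrasts(self, small_trial):
        import copy

        other = copy.deepcopy(small_trial)
        other.arm = "static"
        report = gt.compare_arms(other, small_trial, include_zinb=False)
        cox = report["contrasts"]["cox_time_to_target"]
        assert cox["hr"] == pytest.approx(1.0, abs=1e-6)
        assert report["contrasts"]["in_target_overall"]["pct_a"] == (
            report["contrasts"]["in_target_overall"]["pct_b"]
        )

    def test_report_conserves_counts(self, small_trial):
        import copy

        other = copy.deepcopy(small_trial)
        other.arm = "static"
        report = gt.compare_arms(other, small_trial, include_zinb=False)
        for arm_name, ds in (("static", other), ("dynamic", small_trial)):
            blk = report["arms"][arm_name]
            assert blk["n_measurements"] == ds.n_records
            assert sum(blk["events"]["category_counts"].values()) == ds.n_records
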