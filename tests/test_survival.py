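"""Kaplan-Meier, log-rank and group summaries against hand and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gist_mvd import (
    DomainError,
    cohort_descriptives,
    km_curve,
    logrank_test,
    summarize_groups,
)
from gist_mvd.simulate import reference_partition_cohort
from gist_mvd.survival import round_half_up


class TestKaplanMeier:
    def test_no_deaths_survival_stays_one(self):
        curve = km_curve([1.0, 2.0, 3.0], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_single_death_step(self):
        curve = km_curve([1.0, 2.0, 3.0, 4.0], [True, False, False, False])
        assert curve.survival_at(1.0) == pytest.approx(0.75)

    def test_interleaved_censoring_hand_oracle(self):
        """times 1, 2+, 3, 4+, 5, 6 (+ = censored): hand-computed products.

        S = 5/6, then x3/4, then x1/2, then x0 over the shrinking risk sets.
        """
        times = [1, 2, 3, 4, 5, 6]
        events = [True, False, True, False, True, True]
        curve = km_curve(times, events)
        np.testing.assert_allclose(curve.event_times, [1, 3, 5, 6])
        np.testing.assert_allclose(curve.survival, [5 / 6, 5 / 8, 5 / 16, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [6, 4, 2, 1])

    def test_no_censoring_final_drop_equals_death_fraction(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(2.0, size=40)
        curve = km_curve(times, np.ones(40, dtype=bool))
        assert 1.0 - curve.survival_at(times.max()) == pytest.approx(1.0)

    def test_late_censoring_only_gives_exact_death_fraction(self):
        """When every censoring time exceeds the last death, the curve at the
        last death time is exactly 1 - deaths/n."""
        times = np.array([1.0, 2.0, 3.0, 9.0, 9.5, 10.0])
        events = np.array([True, True, True, False, False, False])
        curve = km_curve(times, events)
        assert curve.survival_at(3.0) == pytest.approx(1.0 - 3 / 6, abs=1e-15)

    def test_tied_death_and_censor_deaths_first(self):
        """A subject censored at a death time is still at risk for that death."""
        curve = km_curve([2.0, 2.0, 3.0], [True, False, False])
        assert curve.at_risk[0] == 3
        assert curve.survival[0] == pytest.approx(2 / 3)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        times = rng.exponential(3.0, 60)
        events = rng.random(60) < 0.6
        curve = km_curve(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )

    def test_negative_times_rejected(self):
        with pytest.raises(DomainError):
            km_curve([-1.0, 2.0], [True, False])

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            km_curve([], [])


def enumeration_logrank(ta, ea, tb, eb):
    """Direct per-death-time hypergeometric enumeration (independent oracle)."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb]).astype(bool)
    group = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    o_minus_e = var = 0.0
    for t in sorted(set(times[events])):
        n = (times >= t).sum()
        na = ((times >= t) & (group == 0)).sum()
        d = ((times == t) & events).sum()
        da = ((times == t) & events & (group == 0)).sum()
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return (o_minus_e**2 / var) if var > 0 else 0.0


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, True, False, True])
        res = logrank_test(t, e, t.copy(), e.copy())
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_small_case_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 5, size=2)
        ta, tb = rng.integers(1, 6, na).astype(float), rng.integers(1, 6, nb).astype(float)
        ea, eb = rng.random(na) < 0.7, rng.random(nb) < 0.7
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(enumeration_logrank(ta, ea, tb, eb))
        assert res.expected["a"] + res.expected["b"] == pytest.approx(
            res.observed["a"] + res.observed["b"]
        )

    def test_zero_deaths_is_uninformative_not_an_error(self):
        res = logrank_test([1.0, 2.0], [False, False], [1.5], [False])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(2, 30), rng.exponential(4, 20)
        ea, eb = rng.random(30) < 0.5, rng.random(20) < 0.5
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(8)
        ta, tb = rng.exponential(2, 50), rng.exponential(5, 25)
        ea, eb = rng.random(50) < 0.7, rng.random(25) < 0.7
        res = logrank_test(ta, ea, tb, eb)
        ref = lifelines_stats.logrank_test(ta, tb, ea, eb)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_permutation_p_close_to_asymptotic(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(1.5, 25), rng.exponential(6.0, 25)
        ea = np.ones(25, dtype=bool)
        res = logrank_test(ta, ea, tb, ea.copy(), permutations=500, seed=0)
        assert res.permutation_p is not None
        assert abs(res.permutation_p - res.p_value) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            logrank_test([], [], [1.0], [True])


class TestSummarizeGroups:
    def test_reference_partition_percentages(self):
        s = summarize_groups(reference_partition_cohort())
        assert s.groups["low"].group_pct == 84.8
        assert s.groups["high"].group_pct == 15.2
        assert s.groups["high"].death_pct == 25.0
        assert s.groups["low"].death_pct == 4.5

    def test_all_low_degenerate_partition(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "mvd_group": ["low", "low"],
                "death_event": [False, True],
            }
        )
        s = summarize_groups(df)
        assert s.groups["low"].group_pct == 100.0
        assert s.groups["high"].group_pct == 0.0

    def test_missing_labels_rejected_and_excluded(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "mvd_group": ["low", None, "high"],
                "death_event": [False, True, True],
            }
        )
        s = summarize_groups(df)
        assert s.rejected_ids == ("b",)
        assert s.n_total == 2

    def test_group_sizes_sum_to_total(self):
        df = reference_partition_cohort()
        s = summarize_groups(df)
        assert s.groups["low"].n + s.groups["high"].n == s.n_total == 79

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            summarize_groups(pd.DataFrame(columns=["patient_id", "mvd_group", "death_event"]))


class TestDescriptives:
    def test_age_mean(self):
        df = reference_partition_cohort().iloc[:3].copy()
        df["age_years"] = [50.0, 60.0, 70.0]
        assert cohort_descriptives(df)["age_mean"] == 60.0

    def test_site_percentages_sum_to_100(self):
        from gist_mvd import CohortSimConfig, generate_cohort

        df = generate_cohort(CohortSimConfig(seed=1))
        pcts = cohort_descriptives(df)["site_pct"]
        assert abs(sum(pcts.values()) - 100.0) < 0.3

    def test_metastasis_percentage(self):
        d = cohort_descriptives(reference_partition_cohort())
        assert d["metastasis_pct"] == 11.4


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(0, 1000, allow_nan=False), st.integers(0, 3))
def test_round_half_up_matches_decimal_convention(value, nd):
    r = round_half_up(value, nd)
    assert abs(r - value) <= 0.5 * 10**-nd + 1e-12
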