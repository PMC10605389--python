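import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from immunoscore import (SurvivalRecord, cox_binary_hr, harrell_c,
                         kaplan_meier, logrank_test, summarize_c)
from immunoscore.survival_stats import _cox_grad_hess, records_to_arrays


def _records(times, events):
    return [SurvivalRecord(str(i), t, e)
            for i, (t, e) in enumerate(zip(times, events))]


def _random_censored(rng, n):
    t = rng.exponential(10, n).round(2) + 0.01
    e = (rng.random(n) > 0.35).astype(int)
    return _records(t, e)


def logrank_oracle(times, events, groups):
    """Textbook observed-minus-expected over hypergeometric variance."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups, int)
    obs = exp = var = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n, n1 = at_risk.sum(), (at_risk & (g == 1)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (g == 1)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var


def harrell_oracle(times, events, scores):
    """Brute-force pair enumeration (protective orientation)."""
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0)
            if not comparable:
                continue
            den += 1
            if scores[j] > scores[i]:
                num += 1
            elif scores[j] == scores[i]:
                num += 0.5
    return num / den


class TestSurvivalRecord:
    def test_zero_time_shifted_with_warning(self):
        with pytest.warns(UserWarning, match="shifted"):
            r = SurvivalRecord("a", 0.0, 1)
        assert r.time == 1e-6

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("a", -1.0, 1)

    def test_event_must_be_binary(self):
        with pytest.raises(ValueError):
            SurvivalRecord("a", 1.0, 2)


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        km = kaplan_meier(_records([1, 2, 3, 4, 5], [0] * 5))
        np.testing.assert_array_equal(km.survival, 1.0)

    def test_hand_product_limit(self):
        km = kaplan_meier(_records([1, 2, 3], [1, 0, 1]))
        np.testing.assert_array_equal(km.event_times, [1.0, 3.0])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.median == 3.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5, 200)
        km = kaplan_meier(_records(t, [1] * 200))
        for u, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((t > u).mean(), abs=1e-12)

    def test_monotone_and_band_brackets_estimate(self, rng):
        km = kaplan_meier(_random_censored(rng, 100))
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(km.ci_lower <= km.survival + 1e-9)
        assert np.all(km.ci_upper >= km.survival - 1e-9)
        assert km.ci_lower.min() >= 0 and km.ci_upper.max() <= 1

    def test_exponential_median_recovered(self):
        rng = np.random.default_rng(77)
        t = rng.exponential(10.5 / np.log(2), 5000)
        km = kaplan_meier(_records(t, [1] * 5000))
        assert km.median == pytest.approx(10.5, abs=0.5)


class TestLogRank:
    def test_identical_groups_null(self):
        base = _records([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        res = logrank_test(base + base, [0] * 6 + [1] * 6)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("times,events,groups", [
        ([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1], [0, 0, 0, 1, 1, 1]),
        ([1, 1, 2, 3, 3, 4], [1, 1, 0, 1, 1, 1], [0, 1, 0, 1, 0, 1]),
    ])
    def test_matches_hand_oracle(self, times, events, groups):
        res = logrank_test(_records(times, events), groups)
        assert res.statistic == pytest.approx(
            logrank_oracle(times, events, groups), abs=1e-9)

    def test_invariant_to_label_swap_and_time_shift(self, rng):
        recs = _random_censored(rng, 60)
        g = rng.integers(0, 2, 60)
        while g.min() == g.max():
            g = rng.integers(0, 2, 60)
        a = logrank_test(recs, g).statistic
        b = logrank_test(recs, 1 - g).statistic
        t, e = records_to_arrays(recs)
        c = logrank_test(_records(t + 7.0, e), g).statistic
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-9)

    def test_power_under_hazard_ratio_two(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(10, 300)
            t1 = rng.exponential(20, 300)
            recs = _records(np.r_[t0, t1], [1] * 600)
            if logrank_test(recs, [0] * 300 + [1] * 300).p_value < 0.001:
                hits += 1
        assert hits >= 19

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_records([1, 2], [1, 1]), [0, 0])


class TestHarrellC:
    def test_all_tied_scores_give_half(self):
        recs = _records([1, 2, 3, 4], [1, 1, 0, 1])
        assert harrell_c(recs, [5, 5, 5, 5]) == 0.5

    def test_perfect_protective_ranking(self):
        recs = _records([2, 4, 6], [1, 1, 1])
        assert harrell_c(recs, [0.1, 0.5, 0.9]) == 1.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            t = rng.integers(1, 15, n).astype(float)  # ties in time too
            e = rng.integers(0, 2, n)
            s = rng.integers(0, 6, n).astype(float)
            recs = _records(t, e)
            try:
                mine = harrell_c(recs, s)
            except ValueError:
                continue  # no comparable pairs
            assert mine == harrell_oracle(t, e, s)

    @given(st.integers(0, 2**31 - 1))
    def test_score_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        s = rng.normal(size=n)  # continuous: no score ties
        recs = _records(t, e)
        assert harrell_c(recs, s) + harrell_c(recs, -s) == pytest.approx(1.0)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c(_records([1, 2], [0, 0]), [1, 2])


class TestSummarizeC:
    def test_zero_variance(self):
        s = summarize_c([0.6, 0.6, 0.6])
        assert (s.mean_c, s.ci_lower, s.ci_upper) == (0.6, 0.6, 0.6)

    def test_two_values(self):
        s = summarize_c([0.5, 0.7])
        half = 1.96 * np.std([0.5, 0.7], ddof=1) / np.sqrt(2)
        assert s.mean_c == pytest.approx(0.6)
        assert s.ci_lower == pytest.approx(0.6 - half)
        assert s.ci_upper == pytest.approx(0.6 + half)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize_c([0.6])


class TestCoxBinaryHR:
    def test_matches_lifelines_on_continuous_times(self, rng):
        from lifelines import CoxPHFitter
        n = 300
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / np.exp(0.7 * x))
        e = (rng.random(n) > 0.3).astype(int)
        res = cox_binary_hr(_records(t, e), x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert res.log_hazard_ratio == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_gradient_vanishes_at_estimate(self, rng):
        recs = _random_censored(rng, 150)
        x = rng.integers(0, 2, 150)
        res = cox_binary_hr(recs, x)
        t, e = records_to_arrays(recs)
        grad, _ = _cox_grad_hess(res.log_hazard_ratio, t, e, x.astype(float))
        assert abs(grad) < 1e-8

    def test_hazard_ratio_consistency(self, rng):
        recs = _random_censored(rng, 100)
        x = rng.integers(0, 2, 100)
        res = cox_binary_hr(recs, x)
        assert res.hazard_ratio == pytest.approx(np.exp(res.log_hazard_ratio))
        assert res.ci_lower <= res.hazard_ratio <= res.ci_upper

    def test_monotone_likelihood_flagged(self):
        recs = _records([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        res = cox_binary_hr(recs, [0, 0, 0, 1, 1, 1])
        assert res.monotone

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="both groups"):
            cox_binary_hr(_records([1, 2], [1, 1]), [0, 0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_binary_hr(_records([1, 2], [0, 0]), [0, 1])
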