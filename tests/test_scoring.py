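import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from immunoscore import (CVPercentileImmunoscore, CVScheme, CutoffSpec,
                         ImmunoscoreResult, TCellDensities, categorize,
                         cv_immunoscore, cv_youden_cutoff,
                         empirical_percentile, pair_percentile_score,
                         youden_cutoff)


def _densities(cd3, cd8, prefix="p"):
    cd3 = np.asarray(cd3, float)
    cd8 = np.asarray(cd8, float)
    return TCellDensities([f"{prefix}{i}" for i in range(cd3.size)], cd3, cd8)


def _random_densities(rng, n):
    cd3 = rng.uniform(0.01, 0.99, n)
    cd8 = cd3 * rng.uniform(0, 1, n)
    return _densities(cd3, cd8)


def counting_percentile(train, q):
    """Independent mid-rank counting oracle."""
    train = list(train)
    below = sum(1 for t in train if t < q)
    at = sum(1 for t in train if t == q)
    return 100.0 * (below + 0.5 * at) / len(train)


def youden_scan_oracle(scores, labels, candidates):
    """Exhaustive threshold scan in exact rational arithmetic."""
    from fractions import Fraction

    best = None
    for c in sorted(candidates):
        tp = sum(1 for s, l in zip(scores, labels) if l == 1 and s < c)
        fn = sum(1 for s, l in zip(scores, labels) if l == 1 and s >= c)
        tn = sum(1 for s, l in zip(scores, labels) if l == 0 and s >= c)
        fp = sum(1 for s, l in zip(scores, labels) if l == 0 and s < c)
        j = Fraction(tp, tp + fn) + Fraction(tn, tn + fp) - 1
        if best is None or j > best[1]:
            best = (c, j)
    return best[0], float(best[1])


class TestEmpiricalPercentile:
    @pytest.mark.parametrize("train,query,expected", [
        ([10, 20, 30, 40], 25, 50.0),
        ([5, 5, 5, 5], 5, 50.0),
        ([1, 2, 3, 4], 10, 100.0),
        ([1, 2, 3, 4], 0, 0.0),
        ([1, 2, 2, 3], 2, 50.0),
    ])
    def test_known_values(self, train, query, expected):
        assert empirical_percentile(train, query) == expected

    def test_matches_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(1, 30)
            train = rng.integers(0, 10, n)  # integers force ties
            q = float(rng.integers(0, 10))
            assert empirical_percentile(train, q) == counting_percentile(train, q)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            empirical_percentile([], 1.0)


class TestPairScore:
    @pytest.mark.parametrize("p3,p8,expected", [(80, 40, 60.0), (0, 0, 0.0),
                                                (100, 100, 100.0)])
    def test_mean(self, p3, p8, expected):
        assert pair_percentile_score(p3, p8) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pair_percentile_score(120, 50)


class TestCVImmunoscore:
    def test_all_tied_cohort_scores_fifty(self):
        dens = _densities([0.2] * 10, [0.1] * 10)
        res = cv_immunoscore(dens, CVScheme(n_iterations=3, seed=0))
        np.testing.assert_array_equal(res.score, 50.0)

    def test_dominating_patient_has_top_score(self, rng):
        dens = _random_densities(rng, 100)
        dens.cd3[7] = dens.cd3.max() + 0.001
        dens.cd8[7] = dens.cd8.max() + 0.001
        res = cv_immunoscore(dens, CVScheme(seed=11))
        assert np.all(res.score[7] > np.delete(res.score, 7))

    def test_deterministic_given_seed(self, rng):
        dens = _random_densities(rng, 40)
        a = cv_immunoscore(dens, CVScheme(seed=5))
        b = cv_immunoscore(dens, CVScheme(seed=5))
        np.testing.assert_array_equal(a.per_iteration_scores, b.per_iteration_scores)

    def test_score_is_iteration_mean_and_bounded(self, rng):
        dens = _random_densities(rng, 30)
        res = cv_immunoscore(dens, CVScheme(seed=2))
        np.testing.assert_allclose(res.score, res.per_iteration_scores.mean(axis=1),
                                   atol=1e-12)
        assert res.score.min() >= 0 and res.score.max() <= 100

    def test_fewer_patients_than_folds_rejected(self):
        dens = _densities([0.1, 0.2], [0.05, 0.1])
        with pytest.raises(ValueError, match="at least 5"):
            cv_immunoscore(dens, CVScheme(n_folds=5))

    def test_event_stratified_folds_keep_both_classes(self, rng):
        dens = _random_densities(rng, 50)
        events = np.r_[np.ones(6, int), np.zeros(44, int)]
        est = CVPercentileImmunoscore(n_iterations=10, random_state=3).fit(
            dens, y=events)
        for it in range(10):
            for f in range(5):
                train = est.folds_[it] != f
                assert events[train].min() == 0 and events[train].max() == 1

    @given(st.integers(0, 10_000))
    def test_rank_preservation_under_dominance(self, seed):
        rng = np.random.default_rng(seed)
        dens = _random_densities(rng, 25)
        i, j = 3, 4
        if dens.cd3[i] >= dens.cd3[j] and dens.cd8[i] >= dens.cd8[j]:
            i, j = j, i  # make j the dominating patient
        dens.cd3[j] = max(dens.cd3[i], dens.cd3[j])
        dens.cd8[j] = max(dens.cd8[i], dens.cd8[j])
        res = cv_immunoscore(dens, CVScheme(n_iterations=5, seed=1))
        assert res.score[j] >= res.score[i]


class TestYoudenCutoff:
    def test_perfect_separation(self):
        cut, j = youden_cutoff([1, 2, 3, 4], [1, 1, 0, 0])
        assert cut == 2.5 and j == 1.0

    def test_tie_breaks_toward_smallest_cutoff(self):
        cut, j = youden_cutoff([1, 2, 3, 4], [1, 0, 1, 0])
        assert cut == 1.5 and j == 0.5

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 12, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max() or np.unique(scores).size < 2:
                continue
            distinct = np.unique(scores)
            cands = (distinct[:-1] + distinct[1:]) / 2
            assert youden_cutoff(scores, labels) == youden_scan_oracle(
                scores, labels, cands)

    def test_independent_labels_give_small_j(self, rng):
        jmax = [youden_cutoff(rng.normal(size=200), rng.integers(0, 2, 200))[1]
                for _ in range(100)]
        assert np.mean(jmax) < 0.25

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            youden_cutoff([1, 2, 3], [1, 1, 1])


class TestCVYoudenCutoff:
    def test_recovers_known_threshold(self, rng):
        n = 300
        dens = _random_densities(rng, n)
        p3 = empirical_percentile(dens.cd3, dens.cd3)
        p8 = empirical_percentile(dens.cd8, dens.cd8)
        true_pct = (p3 + p8) / 2
        deaths = (true_pct < 40).astype(int)
        spec = cv_youden_cutoff(dens, deaths, CVScheme(seed=8))
        assert abs(spec.resolved_percentile - 40) <= 5

    def test_resolved_percentile_in_range(self, rng):
        dens = _random_densities(rng, 60)
        labels = rng.integers(0, 2, 60)
        spec = cv_youden_cutoff(dens, labels, CVScheme(n_iterations=5, seed=3))
        assert 0 < spec.resolved_percentile < 100

    def test_single_class_labels_rejected(self, rng):
        dens = _random_densities(rng, 20)
        with pytest.raises(ValueError, match="both"):
            cv_youden_cutoff(dens, np.ones(20, int), CVScheme(seed=0))


class TestCategorize:
    def _result(self, scores):
        scores = np.asarray(scores, float)
        return ImmunoscoreResult([f"p{i}" for i in range(scores.size)],
                                 scores, scores[:, None])

    def test_quantile_coverage(self, rng):
        res = self._result(rng.uniform(0, 100, 522))
        out = categorize(res, CutoffSpec(percentile=25.0))
        frac_low = (out.category == 0).mean()
        assert frac_low == pytest.approx(0.25, abs=0.04)

    def test_score_at_threshold_is_intermediate_high(self):
        res = self._result([10, 10, 10, 20])
        out = categorize(res, CutoffSpec(percentile=50.0))
        assert out.category.tolist() == [1, 1, 1, 1]

    def test_custom_percentile_coverage(self, rng):
        res = self._result(rng.uniform(0, 100, 1000))
        out = categorize(res, CutoffSpec(percentile=43.5))
        assert (out.category == 0).mean() == pytest.approx(0.435, abs=0.04)

    def test_percentile_bounds_validated(self):
        with pytest.raises(ValueError):
            CutoffSpec(percentile=0.0)
        with pytest.raises(ValueError):
            CutoffSpec(percentile=100.0)

    def test_unresolved_youden_rejected(self):
        res = self._result([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="not resolved"):
            categorize(res, CutoffSpec(method="youden"))
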