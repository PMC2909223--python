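"""CFS merit, feature-class correlation, and subset search strategies."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdzgram import select
from pdzgram.select import (
    CorrelationCache,
    cfs_merit,
    cfs_search,
    consensus_features,
    feature_class_correlation,
    select_features,
)


def exhaustive_best_merit(X, y):
    """Independent oracle: enumerate every non-empty subset directly."""
    n = X.shape[1]
    best, best_subset = -np.inf, ()
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            rcf = np.mean([pearson_abs(X[:, i], label01(y)) for i in subset])
            if k == 1:
                merit = rcf
            else:
                pairs = [pearson_abs(X[:, i], X[:, j])
                         for i, j in itertools.combinations(subset, 2)]
                merit = k * rcf / np.sqrt(k + k * (k - 1) * np.mean(pairs))
            if merit > best + 1e-12:
                best, best_subset = merit, subset
    return best, best_subset


def pearson_abs(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    am, bm = a - a.mean(), b - b.mean()
    return abs(float(am @ bm / np.sqrt((am @ am) * (bm @ bm))))


def label01(y):
    classes = sorted(set(y))
    return np.asarray([c == classes[1] for c in y], dtype=float)


class TestFeatureClassCorrelation:
    def test_column_equal_to_label(self):
        y = ["neg", "pos", "pos", "neg"]
        assert feature_class_correlation(np.array([0, 1, 1, 0.0]), y) == pytest.approx(1.0)

    def test_zero_variance_column_defined_as_zero(self):
        assert feature_class_correlation(np.ones(6), ["a", "b"] * 3) == 0.0

    def test_balanced_orthogonal_column(self):
        # constant within a spurious split, equal means across classes
        col = np.array([1.0, 0.0, 1.0, 0.0])
        assert feature_class_correlation(col, ["a", "a", "b", "b"]) == pytest.approx(0.0)

    def test_matches_direct_pearson_formula(self, rng):
        col = rng.random(20)
        y = rng.choice(["a", "b"], 20)
        if len(set(y)) < 2:
            y[0] = "a"; y[1] = "b"
        assert feature_class_correlation(col, y) == pytest.approx(
            pearson_abs(col, label01(y)))

    def test_multiclass_equals_between_class_variance_ratio(self, rng):
        y = np.repeat(["a", "b", "c"], 10)
        col = rng.random(30) + np.repeat([0.0, 1.0, 3.0], 10)
        grand = col.mean()
        ssb = sum(10 * (col[y == c].mean() - grand) ** 2 for c in "abc")
        sst = ((col - grand) ** 2).sum()
        assert feature_class_correlation(col, y) == pytest.approx(np.sqrt(ssb / sst))


class TestCfsMerit:
    def test_singleton_reduces_to_rcf(self, rng):
        X = rng.random((30, 4))
        y = rng.choice(["a", "b"], 30)
        y[:2] = ["a", "b"]
        for j in range(4):
            assert cfs_merit([j], X, y) == pytest.approx(
                feature_class_correlation(X[:, j], y))

    def test_two_perfect_duplicates_of_label(self):
        y01 = np.array([0, 1, 1, 0, 1, 0.0])
        X = np.column_stack([y01, y01])
        # r_cf = 1, r_ff = 1 -> merit = 2 / sqrt(4) = 1
        assert cfs_merit([0, 1], X, ["n", "p", "p", "n", "p", "n"]) == pytest.approx(1.0)

    def test_zero_rcf_gives_zero_merit(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        assert cfs_merit([0, 1], X, ["a", "b"] * 3) == 0.0

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            cfs_merit([], rng.random((10, 3)), ["a", "b"] * 5)

    @given(scale=st.floats(0.1, 50, allow_nan=False), column=st.integers(0, 3))
    def test_scale_invariance(self, scale, column):
        rng = np.random.default_rng(9)
        X = rng.random((25, 4))
        y = rng.choice(["a", "b"], 25)
        y[:2] = ["a", "b"]
        before = cfs_merit([0, 1, 2, 3], X, y)
        X2 = X.copy()
        X2[:, column] *= scale
        assert cfs_merit([0, 1, 2, 3], X2, y) == pytest.approx(before)


class TestCfsSearch:
    def test_informative_feature_found_among_noise(self, rng):
        y = rng.choice(["n", "p"], 40)
        y[:2] = ["n", "p"]
        X = rng.random((40, 8))
        X[:, 0] = label01(y)
        for strategy in select.STRATEGIES:
            subset = cfs_search(X, y, strategy=strategy)
            assert 0 in subset.indices

    def test_duplicated_informative_feature_kept_once(self, rng):
        y = rng.choice(["n", "p"], 200)
        y[:2] = ["n", "p"]
        noisy = label01(y) + rng.normal(0, 0.1, 200)
        X = np.column_stack([noisy, noisy, rng.random((200, 4))])
        subset = cfs_search(X, y, strategy="best-first")
        assert len({0, 1} & set(subset.indices)) == 1
        # exhaustive enumeration agrees that duplication is penalized
        _, best = exhaustive_best_merit(X, y)
        assert len({0, 1} & set(best)) == 1

    def test_single_feature_input(self, rng):
        y = rng.choice(["n", "p"], 20)
        y[:2] = ["n", "p"]
        X = (label01(y) + rng.normal(0, 0.3, 20)).reshape(-1, 1)
        assert cfs_search(X, y).indices == (0,)

    def test_unknown_strategy_rejected(self, rng):
        with pytest.raises(ValueError, match="strategy"):
            cfs_search(rng.random((10, 2)), ["a", "b"] * 5, strategy="anneal")

    def test_best_first_never_below_greedy(self):
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            n, d = 30, 8
            y = rng.choice(["n", "p"], n)
            y[:2] = ["n", "p"]
            X = rng.random((n, d))
            X[:, 0] = label01(y) + rng.normal(0, 0.5, n)
            bf = cfs_search(X, y, strategy="best-first")
            gf = cfs_search(X, y, strategy="greedy-forward")
            assert bf.merit >= gf.merit - 1e-12

    def test_deterministic(self, rng):
        y = rng.choice(["n", "p"], 30)
        y[:2] = ["n", "p"]
        X = rng.random((30, 6))
        assert cfs_search(X, y) == cfs_search(X, y)


class TestSelectFeatures:
    def test_union_and_intersection(self, rng):
        y = rng.choice(["n", "p"], 40)
        y[:2] = ["n", "p"]
        X = rng.random((40, 6))
        X[:, 2] = label01(y)
        union, subsets = select_features(X, y, combine="union")
        inter, _ = select_features(X, y, combine="intersection")
        assert set(inter) <= set(union)
        assert 2 in union
        assert len(subsets) == 2


class TestConsensusFeatures:
    def test_substring_containment_with_hosts(self):
        out = consensus_features(["125", "612"], ["12", "25", "34"])
        assert out == {"12": ("125", "612"), "25": ("125",)}

    def test_disjoint_sets_empty(self):
        assert consensus_features(["345"], ["12"]) == {}

    def test_repeated_containment_counted_once(self):
        assert consensus_features(["111"], ["11"]) == {"11": ("111",)}

    def test_malformed_gram_rejected(self):
        with pytest.raises(ValueError):
            consensus_features(["128"], ["12"])
        with pytest.raises(ValueError):
            consensus_features(["123"], ["1"])


class TestCacheConsistency:
    def test_cache_merit_matches_oracle_on_small_instances(self):
        for trial in range(10):
            rng = np.random.default_rng(trial)
            y = rng.choice(["n", "p"], 25)
            y[:2] = ["n", "p"]
            X = rng.random((25, 5))
            X[:, 1] = label01(y) + rng.normal(0, 0.4, 25)
            cache = CorrelationCache(X, y)
            for k in (1, 2, 3):
                for subset in itertools.combinations(range(5), k):
                    rcf = np.mean([pearson_abs(X[:, i], label01(y)) for i in subset])
                    if k == 1:
                        expected = rcf
                    else:
                        pairs = [pearson_abs(X[:, i], X[:, j])
                                 for i, j in itertools.combinations(subset, 2)]
                        expected = k * rcf / np.sqrt(k + k * (k - 1) * np.mean(pairs))
                    assert cache.merit(subset) == pytest.approx(expected)
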