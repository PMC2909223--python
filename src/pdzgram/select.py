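"""Correlation-based feature subset selection (CFS) and consensus features.

CFS scores a subset of ``k`` features by

    merit = k * mean(r_cf) / sqrt(k + k (k - 1) * mean(r_ff))

where ``r_cf`` is each member's correlation with the class label and
``r_ff`` the absolute pairwise Pearson correlation between members: a good
subset is highly correlated with the label but internally redundant-free.
Feature-class correlation is the absolute point-biserial (Pearson against
the 0/1 label) for binary tasks and the multiple correlation against a
one-hot label encoding for multi-class tasks; correlations run on the raw
frequency columns without discretization.

Two deterministic search strategies are provided. *Greedy forward*
repeatedly adds the single feature that most improves merit and stops at
the first non-improvement. *Best first* keeps an open list of candidate
subsets ordered by merit, expands the best one by single-feature additions
and removals, and stops after ``stall_limit`` consecutive expansions that
fail to improve the best merit seen; because expansion follows merit
order, it traverses the greedy path first and can only do better.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Sequence as TypingSequence

import numpy as np

__all__ = [
    "FeatureSubset",
    "feature_class_correlation",
    "cfs_merit",
    "cfs_search",
    "select_features",
    "consensus_features",
    "CorrelationCache",
]

STRATEGIES = ("best-first", "greedy-forward")


@dataclass(frozen=True)
class FeatureSubset:
    """A selected feature subset with its merit and provenance."""

    indices: tuple[int, ...]
    merit: float
    strategy: str
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.indices) != sorted(set(self.indices)):
            raise ValueError("indices must be sorted and unique")
        if not np.isfinite(self.merit):
            raise ValueError("merit must be finite")


def _label_matrix(labels: np.ndarray) -> np.ndarray:
    """0/1 column for binary labels, one-hot matrix for multi-class."""
    classes = sorted(set(map(str, labels)))
    if len(classes) < 2:
        raise ValueError("labels must contain at least two classes")
    labels = np.asarray(list(map(str, labels)))
    if len(classes) == 2:
        return (labels == classes[1]).astype(float)[:, None]
    return np.column_stack([(labels == c).astype(float) for c in classes])


def feature_class_correlation(column: np.ndarray, labels: TypingSequence) -> float:
    """Correlation of one feature column with the class label, in [0, 1].

    Binary: absolute Pearson (point-biserial) against the 0/1 label.
    Multi-class: multiple correlation R of the column regressed on the
    one-hot label matrix (equivalently, sqrt of the between-class variance
    fraction). A zero-variance column is defined to have correlation 0.
    """
    column = np.asarray(column, dtype=float)
    if np.ptp(column) == 0:
        return 0.0
    Y = _label_matrix(np.asarray(labels))
    if Y.shape[1] == 1:
        y = Y[:, 0]
        if np.ptp(y) == 0:
            return 0.0
        return float(abs(np.corrcoef(column, y)[0, 1]))
    # R^2 of group-mean prediction = SS_between / SS_total
    total = np.sum((column - column.mean()) ** 2)
    fitted = np.zeros_like(column)
    for j in range(Y.shape[1]):
        mask = Y[:, j] == 1
        fitted[mask] = column[mask].mean()
    between = np.sum((fitted - column.mean()) ** 2)
    return float(np.sqrt(between / total))


class CorrelationCache:
    """Lazy cache of feature-class and feature-feature correlations."""

    def __init__(self, X: np.ndarray, labels: TypingSequence):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.labels = np.asarray(list(map(str, labels)))
        if len(self.labels) != len(self.X):
            raise ValueError("labels length must match X rows")
        self.n_features = self.X.shape[1]
        self._rcf: dict[int, float] = {}
        self._rff: dict[tuple[int, int], float] = {}

    def rcf(self, i: int) -> float:
        if i not in self._rcf:
            self._rcf[i] = feature_class_correlation(self.X[:, i], self.labels)
        return self._rcf[i]

    def rff(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in self._rff:
            a, b = self.X[:, key[0]], self.X[:, key[1]]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                r = 0.0
            else:
                r = abs(float(np.corrcoef(a, b)[0, 1]))
            self._rff[key] = r
        return self._rff[key]

    def merit(self, subset: Iterable[int]) -> float:
        subset = sorted(set(subset))
        if not subset:
            raise ValueError("subset must be non-empty")
        k = len(subset)
        rcf_mean = float(np.mean([self.rcf(i) for i in subset]))
        if k == 1:
            return rcf_mean
        pair_sum = sum(self.rff(subset[a], subset[b])
                       for a in range(k) for b in range(a + 1, k))
        rff_mean = pair_sum / (k * (k - 1) / 2)
        return k * rcf_mean / np.sqrt(k + k * (k - 1) * rff_mean)


def cfs_merit(subset: Iterable[int], X: np.ndarray, labels: TypingSequence) -> float:
    """CFS merit of a feature subset (convenience wrapper over the cache)."""
    return CorrelationCache(X, labels).merit(subset)


def _greedy_forward(cache: CorrelationCache) -> tuple[tuple[int, ...], float]:
    current: list[int] = []
    best_merit = 0.0
    while True:
        best_add, best_add_merit = None, best_merit
        for f in range(cache.n_features):
            if f in current:
                continue
            m = cache.merit(current + [f])
            if m > best_add_merit + 1e-12:
                best_add, best_add_merit = f, m
        if best_add is None:
            break
        current.append(best_add)
        best_merit = best_add_merit
    return tuple(sorted(current)), best_merit


def _best_first(cache: CorrelationCache, stall_limit: int) -> tuple[tuple[int, ...], float]:
    start: tuple[int, ...] = ()
    # heap orders by (-merit, subset) so ties break on the lexicographically
    # smallest subset, i.e. lowest feature indices first
    open_heap: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
    merits: dict[tuple[int, ...], float] = {start: 0.0}
    expanded: set[tuple[int, ...]] = set()
    best_subset, best_merit = start, 0.0
    stall = 0
    while open_heap and stall < stall_limit:
        neg_merit, node = heapq.heappop(open_heap)
        if node in expanded:
            continue
        expanded.add(node)
        improved = False
        node_set = set(node)
        children = [tuple(sorted(node_set | {f}))
                    for f in range(cache.n_features) if f not in node_set]
        children += [tuple(sorted(node_set - {f})) for f in node_set if len(node) > 1]
        for child in children:
            if child in merits:
                continue
            m = cache.merit(child)
            merits[child] = m
            heapq.heappush(open_heap, (-m, child))
            if m > best_merit + 1e-12:
                best_subset, best_merit = child, m
                improved = True
        stall = 0 if improved else stall + 1
    return best_subset, best_merit


def cfs_search(X: np.ndarray, labels: TypingSequence,
               strategy: str = "best-first", seed: int = 0,
               stall_limit: int = 5) -> FeatureSubset:
    """Search for a high-merit feature subset with the given strategy.

    Deterministic given the input; ties always prefer the lowest feature
    index. ``seed`` is recorded as provenance only.
    """
    cache = CorrelationCache(X, labels)
    if cache.n_features < 1:
        raise ValueError("X must have at least one feature")
    if strategy == "greedy-forward":
        indices, merit = _greedy_forward(cache)
    elif strategy == "best-first":
        indices, merit = _best_first(cache, stall_limit)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    return FeatureSubset(indices=indices, merit=merit, strategy=strategy, seed=seed)


def select_features(X: np.ndarray, labels: TypingSequence,
                    strategies: TypingSequence[str] = STRATEGIES,
                    combine: str = "union", seed: int = 0,
                    stall_limit: int = 5) -> tuple[tuple[int, ...], list[FeatureSubset]]:
    """Run all configured strategies and combine their subsets.

    ``combine="union"`` (default) keeps any feature chosen by at least one
    strategy; ``"intersection"`` keeps features all strategies agree on.
    Returns the combined index tuple plus each strategy's own subset.
    """
    if combine not in ("union", "intersection"):
        raise ValueError(f"combine must be union|intersection, got {combine!r}")
    subsets = [cfs_search(X, labels, strategy=s, seed=seed, stall_limit=stall_limit)
               for s in strategies]
    sets = [set(s.indices) for s in subsets]
    combined = set.union(*sets) if combine == "union" else set.intersection(*sets)
    return tuple(sorted(combined)), subsets


def consensus_features(selected_trigrams: Iterable[str],
                       selected_bigrams: Iterable[str]) -> dict[str, tuple[str, ...]]:
    """Bigrams contained in selected trigrams, with their host trigrams.

    Returns each selected bigram occurring as a substring of at least one
    selected trigram, mapped to the sorted tuple of hosts.
    """
    trigrams = sorted(set(selected_trigrams))
    bigrams = sorted(set(selected_bigrams))
    for gram, length in [(g, 3) for g in trigrams] + [(g, 2) for g in bigrams]:
        if len(gram) != length or any(ch not in "1234567" for ch in gram):
            raise ValueError(f"malformed gram {gram!r}")
    out: dict[str, tuple[str, ...]] = {}
    for bg in bigrams:
        hosts = tuple(tg for tg in trigrams if bg in tg)
        if hosts:
            out[bg] = hosts
    return out
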