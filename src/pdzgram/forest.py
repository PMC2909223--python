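"""Random Forest training with supervised resampling and OOB-based tuning.

The reference classifier is a bagged ensemble of decision trees: each tree
grows on a bootstrap sample of the training set and considers a random
subset of ``num_features`` candidate features at every split; prediction is
majority voting over trees, and the vote fraction doubles as a ranking
score for ROC/PR analysis. Out-of-bag (OOB) error — the error of each
instance under the trees whose bootstrap missed it — gives an internal
generalization estimate used for parameter selection, so tuning needs no
held-out set.

Other standard classifiers (nearest neighbour, naive Bayes, single
decision tree, SVM) are exposed through the same train/score contract as
optional backends for comparison harnesses; only the forest carries the
OOB machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .labels import as_arrays

__all__ = [
    "ForestParams",
    "ForestModel",
    "resample",
    "train_forest",
    "train_forest_arrays",
    "predict_score",
    "predict_label",
    "grid_search_oob",
    "save_model",
    "load_model",
    "make_backend",
    "BACKENDS",
]

DEFAULT_TREE_GRID = (10, 50, 100, 200, 500)
DEFAULT_FEATURE_GRID = (5, 10, 20, 30, 50, 100)


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters: ensemble size and per-split feature draw."""

    num_trees: int = 200
    num_features: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_trees < 1:
            raise ValueError("num_trees must be positive")
        if self.num_features < 1:
            raise ValueError("num_features must be positive")


@dataclass
class ForestModel:
    """A trained forest plus the metadata needed to apply it safely."""

    estimator: RandomForestClassifier = field(repr=False)
    classes: tuple[str, ...]
    n_features: int
    oob_error: float
    params: ForestParams


def resample(dataset: TypingSequence, seed: int = 0) -> list:
    """Stratified bootstrap of a labelled instance list.

    Draws with replacement *within* each label so the output has exactly
    the input's per-class counts ("class distribution left as-is"); the
    result is deterministic given ``seed``.
    """
    if not dataset:
        raise ValueError("cannot resample an empty dataset")
    rng = np.random.default_rng(seed)
    labels = np.asarray([inst.label for inst in dataset])
    out_positions = []
    for label in sorted(set(labels)):
        positions = np.flatnonzero(labels == label)
        out_positions.append(rng.choice(positions, size=len(positions), replace=True))
    order = np.concatenate(out_positions)
    rng.shuffle(order)
    return [dataset[i] for i in order]


def train_forest(dataset: TypingSequence, params: ForestParams = ForestParams()) -> ForestModel:
    """Train on a list of instances (see :func:`train_forest_arrays`)."""
    X, y = as_arrays(dataset)
    return train_forest_arrays(X, y, params)


def train_forest_arrays(X: np.ndarray, y: np.ndarray,
                        params: ForestParams = ForestParams()) -> ForestModel:
    """Grow ``num_trees`` bootstrap trees with ``num_features`` split candidates.

    The OOB error recorded on the model is ``1 - OOB accuracy``. Training
    is deterministic given ``params.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if params.num_features > X.shape[1]:
        raise ValueError(f"num_features={params.num_features} exceeds "
                         f"feature dimension {X.shape[1]}")
    estimator = RandomForestClassifier(
        n_estimators=params.num_trees,
        max_features=params.num_features,
        bootstrap=True,
        oob_score=True,
        random_state=params.seed,
        n_jobs=1,
    )
    estimator.fit(X, y.astype(str))
    return ForestModel(
        estimator=estimator,
        classes=classes,
        n_features=X.shape[1],
        oob_error=1.0 - float(estimator.oob_score_),
        params=params,
    )


def _check_matrix(model: ForestModel, vectors: np.ndarray) -> np.ndarray:
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[1] != model.n_features:
        raise ValueError(f"vector dimension {vectors.shape[1]} does not match "
                         f"model dimension {model.n_features}")
    return vectors


def predict_score(model: ForestModel, vectors: np.ndarray) -> np.ndarray:
    """Per-class vote fractions over the trees of the forest.

    Returns an ``(n_samples, n_classes)`` matrix whose columns follow
    ``model.classes``; each row sums to 1. Majority voting over tree
    *labels*, not averaged leaf probabilities, to match the ensemble's
    stated decision rule.
    """
    vectors = _check_matrix(model, vectors)
    counts = np.zeros((len(vectors), len(model.classes)))
    rows = np.arange(len(vectors))
    # sklearn's classes_ is sorted, as is model.classes, so columns line up
    for tree in model.estimator.estimators_:
        vote_idx = np.argmax(tree.predict_proba(vectors), axis=1)
        np.add.at(counts, (rows, vote_idx), 1.0)
    return counts / len(model.estimator.estimators_)


def predict_label(model: ForestModel, vectors: np.ndarray) -> np.ndarray:
    """Majority-vote labels; ties go to the class listed first in ``model.classes``."""
    scores = predict_score(model, vectors)
    return np.asarray([model.classes[j] for j in np.argmax(scores, axis=1)])


def positive_score(model: ForestModel, vectors: np.ndarray, positive: str) -> np.ndarray:
    """Vote fraction of one designated positive class, for ROC/PR sweeps."""
    if positive not in model.classes:
        raise ValueError(f"positive class {positive!r} not in model classes {model.classes}")
    return predict_score(model, vectors)[:, model.classes.index(positive)]


def grid_search_oob(dataset: TypingSequence,
                    tree_grid: TypingSequence[int] = DEFAULT_TREE_GRID,
                    feature_grid: TypingSequence[int] | None = None,
                    seed: int = 0) -> tuple[ForestParams, pd.DataFrame]:
    """Pick (num_trees, num_features) minimizing OOB error over a grid.

    The default feature grid is the fixed ladder {5, 10, 20, 30, 50, 100}
    plus the dimension-aware points d/4 and d/2 (clipped to the feature
    dimension d): when only a handful of informative features hide among
    many noise columns, the OOB optimum can sit far above any fixed
    ladder. Ties break toward the smaller ``num_features``, then the
    smaller ``num_trees``. The full OOB table is returned for reporting.
    """
    if not tree_grid or (feature_grid is not None and not feature_grid):
        raise ValueError("parameter grids must be non-empty")
    X, y = as_arrays(dataset)
    if feature_grid is None:
        d = X.shape[1]
        feature_grid = sorted({f for f in (*DEFAULT_FEATURE_GRID, d // 4, d // 2)
                               if 1 <= f <= d})
    rows = []
    for num_features in sorted(feature_grid):
        for num_trees in sorted(tree_grid):
            params = ForestParams(num_trees=num_trees, num_features=num_features, seed=seed)
            model = train_forest_arrays(X, y, params)
            rows.append({"num_trees": num_trees, "num_features": num_features,
                         "oob_error": model.oob_error})
    table = pd.DataFrame(rows)
    # iteration order makes idxmin respect the tie-break rule
    best = table.loc[table["oob_error"].idxmin()]
    return ForestParams(num_trees=int(best["num_trees"]),
                        num_features=int(best["num_features"]), seed=seed), table


def save_model(model: ForestModel, path) -> None:
    """Persist a model with a small header describing its feature contract."""
    joblib.dump({
        "format": "pdzgram-forest-v1",
        "feature_convention": "lexicographic reduced-alphabet n-grams",
        "n_features": model.n_features,
        "classes": list(model.classes),
        "params": {"num_trees": model.params.num_trees,
                   "num_features": model.params.num_features,
                   "seed": model.params.seed},
        "oob_error": model.oob_error,
        "estimator": model.estimator,
    }, path)


def load_model(path) -> ForestModel:
    blob = joblib.load(path)
    if blob.get("format") != "pdzgram-forest-v1":
        raise ValueError(f"{path}: not a pdzgram forest model file")
    return ForestModel(
        estimator=blob["estimator"],
        classes=tuple(blob["classes"]),
        n_features=int(blob["n_features"]),
        oob_error=float(blob["oob_error"]),
        params=ForestParams(**blob["params"]),
    )


def _make_forest(seed):
    return RandomForestClassifier(n_estimators=200, max_features="sqrt",
                                  oob_score=True, random_state=seed, n_jobs=1)


#: Optional comparison backends sharing the fit/predict_proba contract.
BACKENDS = {
    "forest": _make_forest,
    "knn": lambda seed: KNeighborsClassifier(n_neighbors=3),
    "naive-bayes": lambda seed: GaussianNB(),
    "tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "svm": lambda seed: SVC(probability=True, random_state=seed),
}


def make_backend(name: str, seed: int = 0):
    """Instantiate one of the pluggable comparison classifiers."""
    try:
        return BACKENDS[name](seed)
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; choose from {sorted(BACKENDS)}") from None
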