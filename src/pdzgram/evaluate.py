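"""Confusion metrics, ROC/PR curves, and stratified cross-validation.

Binary evaluation uses the usual confusion-count definitions

    TPR = TP / (TP + FN)        (recall / sensitivity)
    FPR = FP / (FP + TN)        (1 - specificity)
    P   = TP / (TP + FP)        (precision)
    acc = (TP + TN) / total

with any zero-denominator ratio reported as undefined (``None``) rather
than 0. The ROC sweeps thresholds over the distinct scores (ties grouped);
its trapezoid area equals the Mann-Whitney pair-concordance statistic with
half-credit for ties. Cross-validation is stratified and seeded; fold
confusions are pooled (micro-averaged) for the headline metrics and the
per-fold reports are kept alongside.

Multi-class problems report per-class correct/total counts, overall
accuracy, and a class-size-weighted mean of one-vs-rest AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence as TypingSequence

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold

from . import forest as forest_mod
from .forest import ForestParams, predict_score, train_forest_arrays
from .labels import as_arrays

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "confusion_metrics",
    "multiclass_accuracy",
    "roc_curve",
    "pr_curve",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


class Metrics(NamedTuple):
    tpr: float | None
    fpr: float | None
    precision: float | None
    accuracy: float


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """TPR, FPR, precision and accuracy from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty confusion counts")
    return Metrics(
        tpr=_ratio(c.tp, c.tp + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
        precision=_ratio(c.tp, c.tp + c.fp),
        accuracy=(c.tp + c.tn) / c.total,
    )


def multiclass_accuracy(per_class: dict[str, tuple[int, int]]) -> float:
    """Overall accuracy from per-class (correct, total) counts."""
    if not per_class:
        raise ValueError("per-class counts are empty")
    correct = sum(c for c, _ in per_class.values())
    total = sum(t for _, t in per_class.values())
    if total == 0:
        raise ValueError("total count is zero")
    return correct / total


def roc_curve(scores: TypingSequence[float], labels: TypingSequence,
              positive=1) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from (0,0) to (1,1) and the trapezoid AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([lab == positive for lab in labels])
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(skmetrics.auc(fpr, tpr))


def pr_curve(scores: TypingSequence[float], labels: TypingSequence,
             positive=1) -> list[tuple[float, float]]:
    """(recall, precision) per score threshold, recall non-decreasing."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([lab == positive for lab in labels])
    if not y.any():
        raise ValueError("PR curve needs at least one positive")
    precision, recall, _ = skmetrics.precision_recall_curve(y, scores)
    # drop sklearn's artificial (recall 0, precision 1) endpoint, then flip
    # the sweep so recall runs upward
    points = list(zip(recall[:-1].tolist(), precision[:-1].tolist()))
    return points[::-1]


@dataclass
class EvalReport:
    """Evaluation result for one configuration (possibly pooled over folds)."""

    task: str                                   # "binary" or "multiclass"
    confusion: ConfusionCounts | None = None
    metrics: Metrics | None = None
    per_class: dict[str, tuple[int, int]] = field(default_factory=dict)
    accuracy: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "task": self.task,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "pr_points": [list(p) for p in self.pr_points],
            "per_fold": self.per_fold,
        }
        if self.confusion is not None:
            out["confusion"] = {"tp": self.confusion.tp, "fp": self.confusion.fp,
                                "tn": self.confusion.tn, "fn": self.confusion.fn}
        if self.metrics is not None:
            out["metrics"] = dict(self.metrics._asdict())
        if self.per_class:
            out["per_class"] = {k: list(v) for k, v in self.per_class.items()}
        return out


def _binary_confusion(y_true: np.ndarray, y_pred: np.ndarray, positive: str) -> ConfusionCounts:
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
    )


def _weighted_ovr_auc(score_matrix: np.ndarray, y_true: np.ndarray,
                      classes: tuple[str, ...]) -> float:
    """Class-size-weighted mean of one-vs-rest AUCs."""
    aucs, weights = [], []
    for j, cls in enumerate(classes):
        mask = y_true == cls
        if mask.all() or not mask.any():
            continue
        _, auc = roc_curve(score_matrix[:, j], mask, positive=True)
        aucs.append(auc)
        weights.append(mask.sum())
    if not aucs:
        raise ValueError("no class had both positives and negatives")
    return float(np.average(aucs, weights=weights))


def cross_validate(dataset: TypingSequence,
                   k: int = 10,
                   params: ForestParams = ForestParams(),
                   seed: int = 0,
                   positive: str = "binding",
                   resample: str = "none") -> EvalReport:
    """Stratified k-fold cross-validation of the forest on a labelled dataset.

    Every instance is tested exactly once; fold assignment is deterministic
    given ``seed``. ``resample`` controls the supervised bootstrap meant
    for imbalanced data: ``"none"`` (default) disables it, ``"fold"``
    bootstraps each training fold only, ``"pre"`` resamples the whole
    dataset before splitting (the classic pre-process order, which lets
    duplicates straddle folds and leak). On balanced data the bootstrap
    only discards training instances and duplicates label noise, so it is
    opt-in.

    Binary tasks (exactly two labels) pool fold confusions and build ROC/PR
    curves from the pooled positive-class scores; multi-class tasks pool
    per-class correct/total counts and report weighted one-vs-rest AUC.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if resample not in ("fold", "pre", "none"):
        raise ValueError(f"resample must be fold|pre|none, got {resample!r}")
    dataset = list(dataset)
    if resample == "pre":
        dataset = forest_mod.resample(dataset, seed=seed)
    X, y = as_arrays(dataset)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"class {classes[counts.argmin()]!r} has only "
                         f"{counts.min()} instances; use k <= {counts.min()}")
    classes = tuple(classes.tolist())
    binary = len(classes) == 2
    if binary and positive not in classes:
        positive = classes[0]

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(dataset)
    pooled_pred = np.empty(n, dtype=object)
    pooled_scores = np.zeros((n, len(classes)))
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        if resample == "fold":
            train_insts = forest_mod.resample([dataset[i] for i in train_idx],
                                              seed=seed * 1009 + fold)
            X_tr, y_tr = as_arrays(train_insts)
        else:
            X_tr, y_tr = X[train_idx], y[train_idx]
        fold_params = ForestParams(num_trees=params.num_trees,
                                   num_features=params.num_features,
                                   seed=params.seed * 1013 + fold)
        model = train_forest_arrays(X_tr, y_tr, fold_params)
        scores = predict_score(model, X[test_idx])
        # fold model may have seen fewer classes than the full dataset
        full = np.zeros((len(test_idx), len(classes)))
        for j, cls in enumerate(model.classes):
            full[:, classes.index(cls)] = scores[:, j]
        pooled_scores[test_idx] = full
        preds = np.asarray(classes)[np.argmax(full, axis=1)]
        pooled_pred[test_idx] = preds
        fold_acc = float(np.mean(preds == y[test_idx]))
        per_fold.append({"fold": fold, "n_test": int(len(test_idx)), "accuracy": fold_acc})

    pooled_pred = pooled_pred.astype(str)
    if binary:
        confusion = _binary_confusion(y, pooled_pred, positive)
        mets = confusion_metrics(confusion)
        pos_scores = pooled_scores[:, classes.index(positive)]
        roc_points, auc = roc_curve(pos_scores, y, positive=positive)
        pr_points = pr_curve(pos_scores, y, positive=positive)
        return EvalReport(task="binary", confusion=confusion, metrics=mets,
                          accuracy=mets.accuracy, roc_points=roc_points,
                          pr_points=pr_points, auc=auc, per_fold=per_fold)
    per_class = {
        cls: (int(np.sum((y == cls) & (pooled_pred == cls))), int(np.sum(y == cls)))
        for cls in classes
    }
    return EvalReport(task="multiclass", per_class=per_class,
                      accuracy=multiclass_accuracy(per_class),
                      auc=_weighted_ovr_auc(pooled_scores, y, classes),
                      per_fold=per_fold)
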