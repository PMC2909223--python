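"""Confusion metrics, ROC/PR construction, and cross-validation plumbing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdzgram import evaluate, forest
from pdzgram.evaluate import ConfusionCounts, confusion_metrics, multiclass_accuracy
from pdzgram.labels import ClassInstance


def concordance_auc(scores, labels, positive=1):
    """Brute-force Mann-Whitney AUC: concordant pairs, ties half-credit."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_validation_set_worked_example(self):
        # 25 of 27 binding and 46 of 62 non-binding correctly classified
        m = confusion_metrics(ConfusionCounts(tp=25, fn=2, tn=46, fp=16))
        assert m.accuracy == pytest.approx(71 / 89)
        assert m.tpr == pytest.approx(25 / 27)
        assert m.fpr == pytest.approx(16 / 62)
        assert m.precision == pytest.approx(25 / 41)

    def test_perfect_classifier(self):
        assert confusion_metrics(ConfusionCounts(tp=1, tn=1)) == (1.0, 0.0, 1.0, 1.0)

    def test_zero_denominators_undefined_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tn=5, fp=2))
        assert m.tpr is None
        m = confusion_metrics(ConfusionCounts(tp=5, fn=2))
        assert m.fpr is None and m.precision is not None

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestMulticlassAccuracy:
    def test_three_class_worked_example(self):
        per_class = {"I": (43, 45), "II": (16, 20), "I-II": (19, 21)}
        assert multiclass_accuracy(per_class) == pytest.approx(78 / 86)

    def test_all_correct(self):
        assert multiclass_accuracy({"a": (5, 5), "b": (3, 3)}) == 1.0

    def test_none_correct(self):
        assert multiclass_accuracy({"a": (0, 10)}) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            multiclass_accuracy({})


class TestRocCurve:
    def test_perfect_separation(self):
        points, auc = evaluate.roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_constant_scores_random_auc(self):
        _, auc = evaluate.roc_curve([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert auc == 0.5

    def test_interleaved_example(self):
        _, auc = evaluate.roc_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_curve([0.1, 0.2], [1, 1])

    @given(st.data())
    def test_trapezoid_equals_pair_concordance(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n)
                           .filter(lambda ls: 0 < sum(ls) < len(ls)))
        _, auc = evaluate.roc_curve(scores, labels)
        assert auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)


class TestPrCurve:
    def test_perfect_separation_reaches_full_recall_at_full_precision(self):
        points = evaluate.pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (1.0, 1.0) in points
        recalls = [r for r, _ in points]
        assert recalls == sorted(recalls)

    def test_constant_scores_single_point_at_prevalence(self):
        points = evaluate.pr_curve([0.5] * 4, [1, 0, 0, 0])
        assert points == [(1.0, 0.25)]

    def test_interleaved_example_precision_at_full_recall(self):
        # sweeping thresholds by hand: both positives are recovered at
        # thresholds <= 0.4, and the best precision there is 2/3
        points = evaluate.pr_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        at_full = [p for r, p in points if r == 1.0]
        assert max(at_full) == pytest.approx(2 / 3)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            evaluate.pr_curve([0.1, 0.2], [0, 0])


def rule_dataset(n, seed=11, noise=0.0, dim=40, classes=("binding", "non-binding")):
    rng = np.random.default_rng(seed)
    X = rng.random((n, dim))
    if len(classes) == 2:
        y = np.where(X[:, 0] > 0.5, classes[0], classes[1])
    else:
        y = np.asarray(classes)[np.digitize(X[:, 0], [1 / 3, 2 / 3])]
    flip = rng.random(n) < noise
    alt = np.asarray(classes)[(np.searchsorted(classes, y) + 1) % len(classes)]
    y = np.where(flip, alt, y)
    return [ClassInstance(f"s{i}", X[i], str(y[i])) for i in range(n)]


PARAMS = forest.ForestParams(num_trees=30, num_features=10, seed=0)


class TestCrossValidate:
    def test_every_instance_tested_once_pooled_counts(self):
        data = rule_dataset(60)
        report = evaluate.cross_validate(data, k=5, params=PARAMS, seed=0)
        assert report.confusion.total == 60
        assert sum(f["n_test"] for f in report.per_fold) == 60

    def test_leave_one_out(self):
        data = rule_dataset(24)
        k = min(sum(i.label == "binding" for i in data),
                sum(i.label == "non-binding" for i in data))
        report = evaluate.cross_validate(data, k=k, params=PARAMS, seed=0)
        assert report.confusion.total == 24

    def test_stratified_fold_proportions(self):
        data = rule_dataset(100)
        n_pos = sum(i.label == "binding" for i in data)
        report = evaluate.cross_validate(data, k=10, params=PARAMS, seed=0)
        for fold in report.per_fold:
            assert fold["n_test"] in (9, 10, 11)
        # pooled positives must equal the dataset's positives
        assert report.confusion.tp + report.confusion.fn == n_pos

    def test_small_class_rejected_with_hint(self):
        data = rule_dataset(20)
        with pytest.raises(ValueError, match="use k <="):
            evaluate.cross_validate(data, k=15, params=PARAMS, seed=0)

    def test_deterministic_given_seed(self):
        data = rule_dataset(50)
        a = evaluate.cross_validate(data, k=5, params=PARAMS, seed=3).to_dict()
        b = evaluate.cross_validate(data, k=5, params=PARAMS, seed=3).to_dict()
        assert a == b

    def test_planted_rule_recovery_with_noise(self):
        data = rule_dataset(400, noise=0.05)
        report = evaluate.cross_validate(data, k=10, params=PARAMS, seed=0)
        assert report.accuracy >= 0.90

    def test_multiclass_report(self):
        data = rule_dataset(90, classes=("I", "I-II", "II"))
        report = evaluate.cross_validate(data, k=5, params=PARAMS, seed=0)
        assert report.task == "multiclass"
        assert sum(t for _, t in report.per_class.values()) == 90
        assert 0.0 <= report.auc <= 1.0
        assert report.accuracy == multiclass_accuracy(report.per_class)

    def test_resample_modes_accepted(self):
        data = rule_dataset(60)
        for mode in ("none", "fold", "pre"):
            report = evaluate.cross_validate(data, k=5, params=PARAMS,
                                             seed=0, resample=mode)
            assert report.confusion.total == 60
        with pytest.raises(ValueError):
            evaluate.cross_validate(data, k=5, params=PARAMS, seed=0, resample="bogus")


class TestWeightedOvrAuc:
    def test_two_class_ovr_equals_binary_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        y = np.where(rng.random(40) < scores, "binding", "non-binding")
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        matrix = np.column_stack([scores, 1 - scores])
        ovr = evaluate._weighted_ovr_auc(matrix, y, ("binding", "non-binding"))
        _, binary = evaluate.roc_curve(scores, y, positive="binding")
        assert ovr == pytest.approx(binary)
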