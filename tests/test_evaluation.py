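"""Classification metrics against a naive confusion-matrix oracle, and
false-positive counts at recall targets."""

import itertools

import numpy as np
import pytest

from splicescan.dataset import LABEL_ORDER
from splicescan.errors import ConfigError
from splicescan.evaluation import (
    classification_metrics,
    curves,
    fp_at_recall,
    roc_auc,
)
from splicescan.scanner import SiteCall
from splicescan.sequence_io import SpliceSite


def _probs_from_predictions(y_pred, n_classes=3):
    """Degenerate probability rows realizing the given argmax decisions."""
    probs = np.full((len(y_pred), n_classes), 0.05)
    for i, k in enumerate(y_pred):
        probs[i, k] = 0.9
    return probs


def _naive_class_metrics(y_true, y_pred, k):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == k and p == k)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == k and p != k)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != k and p == k)
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    if precision and recall:
        f1 = 2 / (1 / recall + 1 / precision)
    elif recall is None:
        f1 = None
    elif precision is not None:
        f1 = 0.0
    else:
        f1 = None
    return recall, precision, f1


class TestClassificationMetrics:
    def test_printed_formula_arithmetic_case_one(self):
        # donor: TP=8, FN=2, FP=2 -> recall = precision = F1 = 0.8
        donor = LABEL_ORDER.index("donor")
        other = LABEL_ORDER.index("non_splice")
        y_true = [donor] * 10 + [other] * 4
        y_pred = [donor] * 8 + [other] * 2 + [donor] * 2 + [other] * 2
        report = classification_metrics(
            np.array(y_true), _probs_from_predictions(y_pred)
        )
        m = report.per_class["donor"]
        assert (m.recall, m.precision, m.f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_printed_formula_arithmetic_case_two(self):
        # donor: TP=6, FN=4, FP=2 -> recall 0.6, precision 0.75, F1 2/3
        donor = LABEL_ORDER.index("donor")
        other = LABEL_ORDER.index("acceptor")
        y_true = [donor] * 10 + [other] * 5
        y_pred = [donor] * 6 + [other] * 4 + [donor] * 2 + [other] * 3
        report = classification_metrics(
            np.array(y_true), _probs_from_predictions(y_pred)
        )
        m = report.per_class["donor"]
        assert m.recall == pytest.approx(0.6)
        assert m.precision == pytest.approx(0.75)
        assert m.f1 == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        y_true = np.array([0, 1, 2, 0, 1, 2])
        report = classification_metrics(y_true, _probs_from_predictions(y_true))
        assert report.accuracy == 1.0
        assert report.per_class["donor"].auc == 1.0
        assert report.per_class["acceptor"].auc == 1.0

    def test_absent_class_reports_not_applicable(self):
        y_true = np.array([2, 2, 2])
        report = classification_metrics(y_true, _probs_from_predictions([2, 2, 2]))
        assert report.per_class["donor"].recall is None
        assert report.per_class["donor"].auc is None

    def test_exhaustive_confusion_oracle_small_n(self):
        """All (y_true, y_pred) assignments for n <= 4 agree with naive
        counting of the confusion matrix."""
        for n in (1, 2, 3, 4):
            for y_true in itertools.product(range(3), repeat=n):
                for y_pred in itertools.product(range(3), repeat=n):
                    report = classification_metrics(
                        np.array(y_true),
                        _probs_from_predictions(y_pred),
                    )
                    expected_acc = sum(
                        t == p for t, p in zip(y_true, y_pred)
                    ) / n
                    assert report.accuracy == pytest.approx(expected_acc)
                    for name in ("donor", "acceptor"):
                        k = LABEL_ORDER.index(name)
                        recall, precision, f1 = _naive_class_metrics(
                            y_true, y_pred, k
                        )
                        m = report.per_class[name]
                        assert m.recall == pytest.approx(recall)
                        if (np.array(y_true) == k).any():
                            assert m.precision == pytest.approx(precision)
                            assert m.f1 == pytest.approx(f1)

    def test_random_assignments_medium_n_agree_with_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            n = int(rng.integers(5, 9))
            y_true = rng.integers(3, size=n)
            y_pred = rng.integers(3, size=n)
            report = classification_metrics(
                y_true, _probs_from_predictions(y_pred)
            )
            for name in ("donor", "acceptor"):
                k = LABEL_ORDER.index(name)
                recall, _, _ = _naive_class_metrics(list(y_true), list(y_pred), k)
                assert report.per_class[name].recall == pytest.approx(recall)

    def test_bad_prob_shape_rejected(self):
        with pytest.raises(ConfigError):
            classification_metrics(np.array([0, 1]), np.ones((2, 2)))


class TestCurves:
    def test_perfect_separation_gives_auc_one(self):
        y = np.array([0, 0, 1, 1], dtype=bool)
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        roc_points, _ = curves(y, scores)
        fpr, tpr = roc_points
        assert roc_auc(roc_points) == 1.0
        assert any(np.isclose(f, 0) and np.isclose(t, 1) for f, t in zip(fpr, tpr))

    def test_label_independent_scores_give_half_auc(self):
        rng = np.random.default_rng(12)
        y = rng.integers(2, size=5000).astype(bool)
        scores = rng.random(5000)
        roc_points, _ = curves(y, scores)
        assert abs(roc_auc(roc_points) - 0.5) <= 0.03

    def test_single_class_is_not_applicable(self):
        assert curves(np.ones(4, dtype=bool), np.arange(4)) == (None, None)

    def test_report_auc_consistent_with_curve_auc(self):
        rng = np.random.default_rng(5)
        y_true = rng.integers(3, size=60)
        probs = rng.dirichlet(np.ones(3), size=60)
        report = classification_metrics(y_true, probs)
        for name in ("donor", "acceptor"):
            m = report.per_class[name]
            assert m.auc == pytest.approx(roc_auc(m.roc_points))


def _sites(boundaries, site_type="donor"):
    return [SpliceSite("chr1", b, site_type, True) for b in boundaries]


def _calls(items, site_type="donor"):
    return [SiteCall("chr1", b, site_type, s) for b, s in items]


class TestFpAtRecall:
    CALLS = [(10, 0.9), (30, 0.8), (50, 0.6), (70, 0.7)]

    def test_full_recall_needs_lowest_threshold(self):
        report = fp_at_recall(_calls(self.CALLS), _sites([10, 50]), 1.0)
        loc = report.per_type["donor"]
        assert (loc.threshold, loc.fp_count) == (0.6, 2)
        assert report.fp_count == 2

    def test_half_recall_met_at_top_threshold(self):
        report = fp_at_recall(_calls(self.CALLS), _sites([10, 50]), 0.5)
        loc = report.per_type["donor"]
        assert (loc.threshold, loc.fp_count) == (0.9, 0)

    def test_missed_site_makes_target_unattainable(self):
        calls = _calls([(10, 0.9), (30, 0.8)])
        report = fp_at_recall(calls, _sites([10, 50]), 1.0)
        assert not report.attainable
        assert report.fp_count is None
        assert report.per_type["donor"].fp_count is None

    def test_monotone_in_recall_target(self):
        rng = np.random.default_rng(3)
        truth = _sites(sorted(rng.choice(1000, size=10, replace=False) + 50))
        calls = _calls(
            [(int(b), float(s)) for b, s in
             zip(rng.choice(1100, size=60), rng.random(60))]
        ) + _calls([(s.boundary, float(rng.random())) for s in truth])
        previous = -1
        for target in (0.2, 0.4, 0.6, 0.8, 1.0):
            report = fp_at_recall(calls, truth, target)
            if report.attainable:
                assert report.fp_count >= previous
                previous = report.fp_count

    def test_huge_tolerance_matches_everything(self):
        report = fp_at_recall(
            _calls(self.CALLS), _sites([10, 50]), 1.0, tolerance=10**6
        )
        assert report.fp_count == 0

    def test_types_scored_independently(self):
        calls = _calls([(10, 0.9)]) + _calls([(99, 0.3)], "acceptor")
        truth = _sites([10]) + _sites([100], "acceptor")
        report = fp_at_recall(calls, truth, 1.0)
        assert report.per_type["donor"].attainable
        assert not report.per_type["acceptor"].attainable
        assert not report.attainable

    def test_invalid_target_rejected(self):
        with pytest.raises(ConfigError):
            fp_at_recall([], [], 0.0)
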