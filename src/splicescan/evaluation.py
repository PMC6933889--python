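"""Classification and localization metrics.

Window-level classification is scored with accuracy plus one-vs-rest AUC,
recall = TP/(TP+FN), precision = TP/(TP+FP) and the harmonic-mean F1 for
the donor and acceptor classes separately. Long-sequence scans are scored
by the false-positive count at a recall target: sweep the score threshold
from high to low and report the FP count at the most stringent threshold
whose recall of annotated sites reaches the target (the convention behind
"FP at recall 1.0 / 0.8" comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .dataset import ACCEPTOR, DONOR, LABEL_ORDER
from .errors import ConfigError
from .scanner import SiteCall
from .sequence_io import SpliceSite


@dataclass(frozen=True)
class ClassMetrics:
    auc: Optional[float]
    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    roc_points: Optional[tuple] = None  # (fpr, tpr)
    pr_points: Optional[tuple] = None  # (recall, precision)


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    per_class: dict[str, ClassMetrics]

    def to_dict(self) -> dict:
        out = {"accuracy": self.accuracy, "per_class": {}}
        for name, m in self.per_class.items():
            out["per_class"][name] = {
                "auc": m.auc,
                "recall": m.recall,
                "precision": m.precision,
                "f1": m.f1,
            }
        return out


def curves(y_true: np.ndarray, y_scores: np.ndarray):
    """ROC and PR point lists for a binary reduction; None if one class."""
    y_true = np.asarray(y_true).astype(bool)
    if y_true.all() or not y_true.any():
        return None, None
    fpr, tpr, _ = roc_curve(y_true, y_scores)
    prec, rec, _ = precision_recall_curve(y_true, y_scores)
    return (fpr, tpr), (rec[::-1], prec[::-1])


def roc_auc(roc_points) -> Optional[float]:
    if roc_points is None:
        return None
    fpr, tpr = roc_points
    return float(_trapezoid_auc(fpr, tpr))


def classification_metrics(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    label_order: Sequence[str] = LABEL_ORDER,
    positive_classes: Sequence[str] = (DONOR, ACCEPTOR),
) -> ClassificationReport:
    """Score 3-class probabilities at argmax decisions.

    Per-class metrics use the one-vs-rest reduction. A class absent from
    ``y_true`` gets ``None`` metrics (not zero); precision is ``None``
    when the class is never predicted.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    if y_prob.ndim != 2 or y_prob.shape[1] != len(label_order):
        raise ConfigError(
            f"y_prob of shape {y_prob.shape} does not match "
            f"{len(label_order)} classes"
        )
    y_pred = y_prob.argmax(axis=1)
    accuracy = float((y_pred == y_true).mean()) if len(y_true) else float("nan")
    per_class: dict[str, ClassMetrics] = {}
    for name in positive_classes:
        k = list(label_order).index(name)
        pos = y_true == k
        pred_pos = y_pred == k
        if not pos.any():
            per_class[name] = ClassMetrics(None, None, None, None)
            continue
        tp = int((pos & pred_pos).sum())
        fn = int((pos & ~pred_pos).sum())
        fp = int((~pos & pred_pos).sum())
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if (tp + fp) else None
        if precision and recall:
            f1 = 2.0 / (1.0 / recall + 1.0 / precision)
        elif precision is not None:
            f1 = 0.0
        else:
            f1 = None
        roc_points, pr_points = curves(pos, y_prob[:, k])
        per_class[name] = ClassMetrics(
            auc=roc_auc(roc_points),
            recall=recall,
            precision=precision,
            f1=f1,
            roc_points=roc_points,
            pr_points=pr_points,
        )
    return ClassificationReport(accuracy=accuracy, per_class=per_class)


@dataclass(frozen=True)
class TypeLocalization:
    recall_target: float
    achieved_recall: Optional[float]
    fp_count: Optional[int]
    threshold: Optional[float]
    attainable: bool


@dataclass(frozen=True)
class LocalizationReport:
    recall_target: float
    per_type: dict[str, TypeLocalization]
    fp_count: Optional[int]  # combined, at each type's own threshold
    attainable: bool

    def to_dict(self) -> dict:
        return {
            "recall_target": self.recall_target,
            "fp_count": self.fp_count,
            "attainable": self.attainable,
            "per_type": {
                t: {
                    "achieved_recall": loc.achieved_recall,
                    "fp_count": loc.fp_count,
                    "threshold": loc.threshold,
                    "attainable": loc.attainable,
                }
                for t, loc in self.per_type.items()
            },
        }


def _match_matrix(
    calls: Sequence[SiteCall],
    boundaries: Sequence[int],
    tolerance: int,
) -> list[Optional[int]]:
    """For each call, the index of a matching true boundary (or None)."""
    order = np.argsort(boundaries)
    sorted_b = np.asarray(boundaries)[order]
    matches: list[Optional[int]] = []
    for call in calls:
        i = int(np.searchsorted(sorted_b, call.boundary))
        hit = None
        for j in (i - 1, i):
            if 0 <= j < len(sorted_b) and abs(int(sorted_b[j]) - call.boundary) <= tolerance:
                hit = int(order[j])
                break
        matches.append(hit)
    return matches


def fp_at_recall(
    calls: Sequence[SiteCall],
    true_sites: Sequence[SpliceSite],
    recall_target: float,
    tolerance: int = 0,
) -> LocalizationReport:
    """False positives at the most stringent threshold reaching a recall.

    Computed per site type over a high-to-low sweep of the observed call
    scores; ``attainable`` is False when even threshold 0 (all calls)
    misses the target. The combined count sums the per-type counts at each
    type's own threshold.
    """
    if not (0 < recall_target <= 1):
        raise ConfigError("recall_target must lie in (0, 1]")
    per_type: dict[str, TypeLocalization] = {}
    site_types = sorted({s.site_type for s in true_sites})
    for site_type in site_types:
        truth = [s.boundary for s in true_sites if s.site_type == site_type]
        type_calls = [c for c in calls if c.site_type == site_type]
        matches = _match_matrix(type_calls, truth, tolerance)
        scores = np.array([c.score for c in type_calls])
        best = None
        for threshold in sorted(set(scores), reverse=True):
            keep = scores >= threshold
            matched = {m for m, k in zip(matches, keep) if k and m is not None}
            recall = len(matched) / len(truth) if truth else 1.0
            n_fp = int(sum(1 for m, k in zip(matches, keep) if k and m is None))
            if recall >= recall_target:
                best = TypeLocalization(
                    recall_target, recall, n_fp, float(threshold), True
                )
                break
        if best is None:
            best = TypeLocalization(recall_target, None, None, None, False)
        per_type[site_type] = best
    attainable = bool(per_type) and all(t.attainable for t in per_type.values())
    combined = (
        int(sum(t.fp_count for t in per_type.values())) if attainable else None
    )
    return LocalizationReport(
        recall_target=recall_target,
        per_type=per_type,
        fp_count=combined,
        attainable=attainable,
    )
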