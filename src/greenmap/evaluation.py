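"""Confusion matrices and the classifier metric suite.

Two accuracy notions are computed side by side and must not be conflated:

- ``overall_accuracy``: trace/total, the usual fraction of correctly
  classified tiles; for single-label multiclass data this coincides exactly
  with micro-averaged precision and recall.
- ``macro_accuracy``: each class is reduced to a binary (one-vs-rest)
  problem, its binary accuracy (tp+tn)/(tp+fn+fp+tn) computed, and the l
  per-class accuracies averaged. For l > 2 this generally differs from
  overall accuracy (it counts true negatives), and it equals overall
  accuracy when l = 2 or the matrix is diagonal.

Micro precision/recall pool tp/fp/fn over all classes before dividing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "overall_accuracy",
    "macro_accuracy",
    "micro_metrics",
    "normalize_rows",
    "evaluate",
]


@dataclasses.dataclass
class ConfusionMatrix:
    """An l x l count table; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        l = len(self.class_order)
        if counts.shape != (l, l):
            raise ValueError(f"counts shape {counts.shape} does not match {l} classes")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        self.counts = counts

    @property
    def l(self) -> int:
        return len(self.class_order)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fn - self.fp

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order).to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(), tuple(frame.columns))


def confusion_matrix(
    true_codes: Sequence[str],
    predicted_codes: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Tally ``counts[i, j] = #(true == class i and predicted == class j)``."""
    if len(true_codes) != len(predicted_codes):
        raise ValueError(
            f"length mismatch: {len(true_codes)} true vs {len(predicted_codes)} predicted"
        )
    order = tuple(class_order)
    known = set(order)
    unknown = (set(true_codes) | set(predicted_codes)) - known
    if unknown:
        raise ValueError(f"codes outside class order: {sorted(unknown)}")
    if len(true_codes) == 0:
        return ConfusionMatrix(np.zeros((len(order), len(order)), dtype=np.int64), order)
    counts = _sk_confusion_matrix(list(true_codes), list(predicted_codes), labels=list(order))
    return ConfusionMatrix(counts, order)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct classifications: trace / total."""
    if cm.total == 0:
        raise ValueError("accuracy undefined on an empty confusion matrix")
    return float(cm.tp.sum() / cm.total)


def macro_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of the l one-vs-rest binary accuracies.

    ``(1/l) * sum_i (tp_i + tn_i) / (tp_i + fn_i + fp_i + tn_i)``. Not the
    same quantity as trace/total when l > 2.
    """
    if cm.total == 0:
        raise ValueError("accuracy undefined on an empty confusion matrix")
    per_class = (cm.tp + cm.tn) / (cm.tp + cm.fn + cm.fp + cm.tn)
    return float(per_class.mean())


def micro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1).

    tp/fp/fn are pooled over classes before dividing. For single-label
    multiclass data every misclassification is simultaneously one fp and
    one fn, so micro precision = micro recall = overall accuracy.
    """
    if cm.total == 0:
        raise ValueError("micro metrics undefined on an empty confusion matrix")
    tp_sum = cm.tp.sum()
    prec_den = tp_sum + cm.fp.sum()
    rec_den = tp_sum + cm.fn.sum()
    if prec_den == 0 or rec_den == 0:
        raise ValueError("micro metrics undefined: zero tp+fp or tp+fn denominator")
    precision = float(tp_sum / prec_den)
    recall = float(tp_sum / rec_den)
    if precision + recall == 0:
        raise ValueError("F1 undefined: precision + recall is zero")
    f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def normalize_rows(cm: ConfusionMatrix) -> np.ndarray:
    """Row-stochastic matrix: each nonzero row divided by its row sum.

    Diagonal entries are per-class recalls; zero rows stay zero.
    """
    counts = cm.counts.astype(np.float64)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, 0.0)
    return normalized


@dataclasses.dataclass
class MetricsReport:
    """Full metric suite for one evaluation run."""

    overall_accuracy: float
    macro_accuracy: float
    micro_precision: float
    micro_recall: float
    f1_micro: float
    per_class_recall: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def evaluate(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the full report from a confusion matrix."""
    precision, recall, f1 = micro_metrics(cm)
    diag = np.diag(normalize_rows(cm))
    return MetricsReport(
        overall_accuracy=overall_accuracy(cm),
        macro_accuracy=macro_accuracy(cm),
        micro_precision=precision,
        micro_recall=recall,
        f1_micro=f1,
        per_class_recall={c: float(d) for c, d in zip(cm.class_order, diag)},
    )
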