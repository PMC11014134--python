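"""Classification metrics and confusion-matrix arithmetic.

Metrics follow the one-vs-rest reading of precision, recall, F1 and accuracy:

    precision_k = TP_k / (TP_k + FP_k)
    recall_k    = TP_k / (TP_k + FN_k)
    F1_k        = 2 * precision_k * recall_k / (precision_k + recall_k)
    accuracy    = trace / total            (multi-class reduction)

all reported in percent. ``metrics_from_normalized`` evaluates the same
quantities directly from a *row-normalized percentage* confusion matrix under
equal class priors (balanced test sets), which is how published results
tables are typically laid out: the row-normalized diagonal is the per-class
recall, a column-normalized diagonal entry is the precision, and the diagonal
mean is the overall accuracy. Printed matrices are rounded, so row sums in
[99.5, 100.5] are tolerated and values are deliberately *not* re-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    matrix: np.ndarray
    class_labels: list
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.class_labels)
        if self.matrix.shape != (k, k):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {k} labels"
            )
        if np.any(self.matrix < 0):
            raise ValueError("confusion matrix entries must be nonnegative")
        if self.normalized:
            sums = self.matrix.sum(axis=1)
            if np.any(sums < 99.5) or np.any(sums > 100.5):
                raise ValueError(
                    f"row sums {sums} outside the rounding tolerance [99.5, 100.5]"
                )


@dataclass
class MetricsReport:
    class_labels: list
    precision: np.ndarray   # percent
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    zero_division_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def macro(self) -> dict[str, float]:
        return {
            "precision": float(self.precision.mean()),
            "recall": float(self.recall.mean()),
            "f1": float(self.f1.mean()),
            "accuracy": self.accuracy,
        }

    def as_dict(self) -> dict:
        return {
            "labels": list(self.class_labels),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
        }


def confusion_from_predictions(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Counts matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        for v in arr:
            if v not in index:
                raise ValueError(f"unknown label {v!r} in {name}")
    k = len(labels)
    m = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return ConfusionMatrix(matrix=m, class_labels=list(labels))


def _prf(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray):
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0) * 100.0
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0) * 100.0
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    flags = (tp + fp == 0) | (tp + fn == 0)
    return precision, recall, f1, flags


def metrics_from_counts(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest metrics and overall accuracy from raw counts."""
    m = cm.matrix
    if cm.normalized:
        raise ValueError("metrics_from_counts expects a counts matrix")
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    precision, recall, f1, flags = _prf(tp, fp, fn)
    accuracy = float(np.trace(m) / total * 100.0)
    return MetricsReport(class_labels=list(cm.class_labels), precision=precision,
                         recall=recall, f1=f1, accuracy=accuracy,
                         zero_division_flags=flags)


def metrics_from_normalized(cm: ConfusionMatrix, balanced: bool = True) -> MetricsReport:
    """Metrics from a row-normalized percentage matrix under equal priors.

    With balanced classes each row carries equal weight, so the row-normalized
    percentages act as counts: recall_k is the diagonal entry, precision_k is
    the diagonal entry over its column sum, and accuracy is the diagonal mean.
    """
    if not balanced:
        raise ValueError(
            "metrics from a row-normalized matrix are only defined under "
            "equal class priors; pass balanced=True or use counts"
        )
    m = ConfusionMatrix(cm.matrix, cm.class_labels, normalized=True).matrix
    tp = np.diag(m)
    col = m.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / col, 0.0) * 100.0
        # rows are percentages of each true class: recall is the diagonal as
        # printed (rounded row sums are NOT re-normalized away)
        recall = tp.copy()
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    flags = col == 0
    accuracy = float(np.mean(tp))
    return MetricsReport(class_labels=list(cm.class_labels), precision=precision,
                         recall=recall, f1=f1, accuracy=accuracy,
                         zero_division_flags=flags)


def normalize_rows(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Convert a counts matrix to row percentages."""
    m = cm.matrix
    sums = m.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("cannot normalize rows that sum to zero")
    return ConfusionMatrix(matrix=m / sums * 100.0,
                           class_labels=list(cm.class_labels), normalized=True)
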