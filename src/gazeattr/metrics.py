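"""Confusion counts and classification metrics.

Accuracy = correct / total, Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2PR/(P+R).  Ratios with a zero denominator are reported as 0 and the
metric name is recorded in ``flags`` rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "flags": list(self.flags),
        }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) with the ASD class (label 1) as positive."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have the same shape")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    flags: list[str] = []
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("no samples")
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        precision = 0.0
        flags.append("precision_undefined")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        flags.append("recall_undefined")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        flags.append("f1_undefined")
    else:
        f1 = f1_from_pr(precision, recall)
    return MetricsReport(tp, fp, fn, tn, accuracy, precision, recall, f1, flags)


def report_from_predictions(y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Hard-threshold probabilities and compute the full report."""
    y_pred = (np.asarray(proba) >= threshold).astype(int)
    return metrics_from_counts(*confusion_counts(y_true, y_pred))
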