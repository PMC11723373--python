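"""Seizure prediction/detection metrics and cross-validation.

Sensitivity = TP / (TP + FN), per-sample FPR = FP / (TN + FP), accuracy =
correct / total (trace / total in the multiclass case). Because a
per-sample ratio cannot express alarms per hour, the per-hour false-positive
rate counts false-alarm *events* — consecutive positive interictal samples
merged within a refractory window — divided by the monitored interictal
hours. The prediction time of a seizure is the interval between the first
positively classified preictal sample and the annotated onset; an onset
counts as predicted when at least one preictal sample is classified
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "sensitivity",
    "false_positive_rate",
    "false_alarms_per_hour",
    "accuracy",
    "prediction_time",
    "kfold_split",
    "evaluate_binary",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; ``matrix`` carries the full n x n table."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    matrix: np.ndarray | None = None

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self):
        if self.matrix is not None:
            return int(self.matrix.sum())
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    sensitivity: float
    fpr: float
    accuracy: float
    confusion: ConfusionCounts
    fpr_per_hour: float | None = None
    prediction_times_min: list = field(default_factory=list)
    missed_events: int = 0


def confusion_counts(y_true, y_pred, n_classes=None):
    """Counts from labels; binary fills TP/FP/TN/FN (positive class = 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.arange(n_classes) if n_classes else np.arange(
        max(y_true.max(initial=0), y_pred.max(initial=0)) + 1
    )
    m = _sk_confusion(y_true, y_pred, labels=labels)
    if len(labels) == 2:
        tn, fp, fn, tp = m.ravel()
        return ConfusionCounts(TP=int(tp), FP=int(fp), TN=int(tn),
                               FN=int(fn), matrix=m)
    return ConfusionCounts(matrix=m)


def sensitivity(c):
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive samples")
    return c.TP / (c.TP + c.FN)


def false_positive_rate(c, hours=None):
    """Per-sample FPR; with ``hours`` also returns FP-count / hours.

    The per-hour form here is the raw sample-count rate; use
    :func:`false_alarms_per_hour` for the event-merged alarm rate.
    """
    if c.TN + c.FP == 0:
        raise ZeroDivisionError("FPR undefined: no negative samples")
    per_sample = c.FP / (c.TN + c.FP)
    if hours is None:
        return per_sample
    if hours <= 0:
        raise ValueError("hours must be positive")
    return per_sample, c.FP / hours


def false_alarms_per_hour(times_s, positives, hours, refractory_s=120.0):
    """Event-rate FPR: merge positive interictal samples closer than
    ``refractory_s`` into single alarms, divide by monitored hours."""
    if hours <= 0:
        raise ValueError("hours must be positive")
    times = np.asarray(times_s, dtype=float)[np.asarray(positives, bool)]
    if times.size == 0:
        return 0.0
    times = np.sort(times)
    events = 1 + int(np.sum(np.diff(times) > refractory_s))
    return events / hours


def accuracy(c):
    if c.total == 0:
        raise ZeroDivisionError("accuracy undefined on empty counts")
    if c.matrix is not None:
        return float(np.trace(c.matrix) / c.matrix.sum())
    return (c.TP + c.TN) / c.total


def prediction_time(times_s, scores, onset_s, threshold=0.5):
    """Minutes between the first positive preictal sample and onset.

    ``times_s`` are sample timestamps (all before onset), ``scores`` the
    positive-class scores. Returns None when no sample crosses the
    threshold (the event is missed).
    """
    times = np.asarray(times_s, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if np.any(times > onset_s):
        raise ValueError("preictal samples must precede the onset")
    order = np.argsort(times)
    pos = scores[order] >= threshold
    if not pos.any():
        return None
    first = times[order][np.argmax(pos)]
    return (onset_s - first) / 60.0


def kfold_split(labels, k=10, rng=None, groups=None):
    """Stratified k-fold index partitions (seeded, disjoint, covering).

    With ``groups`` (e.g. one id per seizure event) samples sharing a group
    are kept within a single fold, guarding against leakage of one
    seizure's preictal window across train and test.
    """
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError("fewer samples than folds")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"a class has only {counts.min()} members; use k <= {counts.min()}"
        )
    seed = int(np.random.default_rng(rng).integers(2**31))
    if groups is not None:
        from sklearn.model_selection import StratifiedGroupKFold

        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        return list(splitter.split(np.zeros(len(labels)), labels, groups))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(labels)), labels))


def evaluate_binary(y_true, scores, threshold=0.5, interictal_hours=None,
                    times_s=None, refractory_s=120.0):
    """Sample-level binary evaluation; optionally the event FPR/h when the
    interictal samples carry timestamps and a monitored duration."""
    y_true = np.asarray(y_true)
    y_pred = (np.asarray(scores) >= threshold).astype(int)
    c = confusion_counts(y_true, y_pred, n_classes=2)
    fph = None
    if interictal_hours is not None and times_s is not None:
        neg = y_true == 0
        fph = false_alarms_per_hour(
            np.asarray(times_s)[neg], y_pred[neg] == 1, interictal_hours,
            refractory_s,
        )
    return EvalReport(
        sensitivity=sensitivity(c),
        fpr=false_positive_rate(c),
        accuracy=accuracy(c),
        confusion=c,
        fpr_per_hour=fph,
    )
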