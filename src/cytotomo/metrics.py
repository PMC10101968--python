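"""Confusion matrices and classification metrics.

All rates are reported as percentages rounded half-up to one decimal
(0.9375 → 93.8), matching the convention of published classification
tables, and the Matthews correlation coefficient is likewise scaled by
100. A binary matrix yields the full nine-statistic report for *each*
class taken as positive; an N-class matrix yields the overall accuracy
plus one-vs-rest binary reports per class.

Statistics, for a 2x2 matrix with TP/FN in the positive-class row:

========================  =================================================
accuracy                  (TP + TN) / total
recall / TPR              TP / (TP + FN)
specificity / TNR         TN / (TN + FP)
precision / PPV           TP / (TP + FP)
NPV                       TN / (TN + FN)
balanced accuracy         (TPR + TNR) / 2
F1                        2·TP / (2·TP + FP + FN)
MCC                       (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
Fowlkes–Mallows           √(PPV · TPR)
========================  =================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

METRIC_NAMES = (
    "accuracy",
    "recall",
    "specificity",
    "precision",
    "npv",
    "balanced_accuracy",
    "f1",
    "mcc",
    "fowlkes_mallows",
)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (93.75 → 93.8), unlike banker's rounding."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class ConfusionMatrix:
    """Labeled count matrix: rows are true classes, columns predictions."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = tuple(self.classes)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {self.counts.shape}")
        if len(self.classes) != self.counts.shape[0]:
            raise ValueError("class labels must match matrix size")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse(self, positive: str) -> "ConfusionMatrix":
        """One-vs-rest 2x2 matrix with `positive` as the first class."""
        i = self.classes.index(positive)
        tp = self.counts[i, i]
        fn = self.counts[i].sum() - tp
        fp = self.counts[:, i].sum() - tp
        tn = self.total - tp - fn - fp
        return ConfusionMatrix(
            np.array([[tp, fn], [fp, tn]]), (positive, f"not-{positive}")
        )


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Count matrix with counts[i][j] = #(true class i predicted as j)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order),) * 2, dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label: {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label: {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


@dataclass
class MetricReport:
    """Overall accuracy plus the per-class statistics of a confusion matrix.

    ``per_class[label][metric]`` holds percentages rounded half-up to one
    decimal; a metric whose denominator vanishes is reported as None and
    the reason recorded in ``undefined``.
    """

    accuracy: float
    per_class: dict[str, dict[str, float | None]]
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "undefined": self.undefined,
        }

    def to_table(self) -> str:
        """Plain-text table: metrics as rows, classes as columns."""
        classes = list(self.per_class)
        width = max(len("balanced_accuracy"), *(len(c) for c in classes)) + 2
        lines = ["".join(["metric".ljust(20)] + [c.rjust(width) for c in classes])]
        lines.append("accuracy".ljust(20) + f"{self.accuracy:>{width}.1f}")
        for m in METRIC_NAMES[1:]:
            row = [m.ljust(20)]
            for c in classes:
                v = self.per_class[c][m]
                row.append(("n/a" if v is None else f"{v:.1f}").rjust(width))
            lines.append("".join(row))
        return "\n".join(lines)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def _binary_stats(tp: int, fn: int, fp: int, tn: int) -> dict[str, float | None]:
    total = tp + fn + fp + tn
    tpr = _ratio(tp, tp + fn)
    tnr = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    out: dict[str, float | None] = {
        "accuracy": _ratio(tp + tn, total),
        "recall": tpr,
        "specificity": tnr,
        "precision": ppv,
        "npv": npv,
        "balanced_accuracy": None if tpr is None or tnr is None else (tpr + tnr) / 2,
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
        "mcc": None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
        "fowlkes_mallows": None
        if ppv is None or tpr is None
        else math.sqrt(ppv * tpr),
    }
    return out


def _rounded(stats: dict[str, float | None]) -> dict[str, float | None]:
    return {
        k: None if v is None else round_half_up(100.0 * v) for k, v in stats.items()
    }


def binary_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Full nine-statistic report for each class of a 2x2 matrix.

    The two per-class reports are mirror images: the TNR of class 1 equals
    the TPR of class 2 and NPV_1 = PPV_2, which is asserted here as a
    consistency check.
    """
    if cm.counts.shape != (2, 2):
        raise ValueError(f"binary_metrics requires a 2x2 matrix, got {cm.counts.shape}")
    (tp, fn), (fp, tn) = cm.counts
    per_class: dict[str, dict[str, float | None]] = {}
    undefined: dict[str, str] = {}
    stats_pos = _binary_stats(tp, fn, fp, tn)
    stats_neg = _binary_stats(tn, fp, fn, tp)
    for label, stats in ((cm.classes[0], stats_pos), (cm.classes[1], stats_neg)):
        per_class[label] = _rounded(stats)
        for k, v in stats.items():
            if v is None:
                undefined[f"{label}.{k}"] = "zero denominator"
    acc = stats_pos["accuracy"]
    if acc is None:
        raise ValueError("empty confusion matrix")
    return MetricReport(round_half_up(100.0 * acc), per_class, undefined)


def multiclass_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Overall accuracy plus one-vs-rest binary statistics per class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.counts.shape == (2, 2):
        return binary_metrics(cm)
    per_class: dict[str, dict[str, float | None]] = {}
    undefined: dict[str, str] = {}
    for label in cm.classes:
        (tp, fn), (fp, tn) = cm.collapse(label).counts
        stats = _binary_stats(tp, fn, fp, tn)
        per_class[label] = _rounded(stats)
        for k, v in stats.items():
            if v is None:
                undefined[f"{label}.{k}"] = "zero denominator"
    acc = np.trace(cm.counts) / cm.total
    return MetricReport(round_half_up(100.0 * acc), per_class, undefined)


def cm_from_recalls(
    recalls_pct: Sequence[float],
    class_sizes: Sequence[int],
    classes: Sequence[str] = ("positive", "negative"),
) -> ConfusionMatrix:
    """Reconstruct the unique 2x2 matrix consistent with printed recalls.

    With per-class recalls given to one decimal and known class sizes, the
    diagonal is TP_i = round(recall_i · n_i / 100) (ties away from zero)
    and the residual of each row falls in the single off-diagonal cell.
    """
    if len(recalls_pct) != 2 or len(class_sizes) != 2:
        raise ValueError("cm_from_recalls handles the binary case only")
    for r in recalls_pct:
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"recall {r} outside [0, 100]")
    tps = [
        int(round_half_up(r * n / 100.0, decimals=0))
        for r, n in zip(recalls_pct, class_sizes)
    ]
    counts = np.array(
        [[tps[0], class_sizes[0] - tps[0]], [class_sizes[1] - tps[1], tps[1]]]
    )
    return ConfusionMatrix(counts, tuple(classes))
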