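"""Classification metrics: confusion matrix, per-class precision/recall/F1,
accuracy, weighted and macro averages, and a formatted classification report.

Conventions: confusion entry (i, j) counts true-class-i samples predicted as
class j; precision (recall) is 0 when a class has no predicted (true)
instances; weighted averages use class supports as weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ClassMetrics",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "classification_report",
]


@dataclass
class ClassMetrics:
    name: str
    tp: int
    fp: int
    fn: int
    support: int
    precision: float
    recall: float
    f1: float


@dataclass
class MetricsReport:
    confusion: np.ndarray
    per_class: list[ClassMetrics]
    accuracy: float
    weighted: dict[str, float]
    macro: dict[str, float]
    class_names: list[str]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def table(self) -> str:
        """Formatted report: one row per class plus a weighted-average row."""
        width = max(12, max((len(c.name) for c in self.per_class), default=12))
        lines = [f"{'Class name':<{width}}  Precision  Recall  F1 score  Support"]
        for c in self.per_class:
            lines.append(
                f"{c.name:<{width}}  {c.precision:9.4f}  {c.recall:6.4f}  {c.f1:8.4f}  {c.support:7d}"
            )
        n = int(self.confusion.sum())
        lines.append(
            f"{'Weighted Avg':<{width}}  {self.weighted['precision']:9.4f}  "
            f"{self.weighted['recall']:6.4f}  {self.weighted['f1']:8.4f}  {n:7d}"
        )
        lines.append(f"Accuracy: {self.accuracy:.4f}")
        return "\n".join(lines)


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """C x C count matrix with rows indexing the true class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have the same length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(num_classes)).astype(np.int64)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return out


def per_class_metrics(confusion: np.ndarray, class_names: list[str] | None = None):
    """Precision, recall and F1 per class plus overall accuracy.

    Precision_c = TP_c / (TP_c + FP_c), Recall_c = TP_c / (TP_c + FN_c),
    F1 their harmonic mean, accuracy = trace / N; undefined ratios are 0.
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if confusion.sum() == 0:
        raise ValueError("confusion matrix is empty (no samples)")
    c = confusion.shape[0]
    names = class_names if class_names is not None else [f"class_{i}" for i in range(c)]
    tp = np.diag(confusion).astype(np.float64)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    support = confusion.sum(axis=1)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    accuracy = float(tp.sum() / confusion.sum())
    per_class = [
        ClassMetrics(
            name=names[i],
            tp=int(tp[i]),
            fp=int(fp[i]),
            fn=int(fn[i]),
            support=int(support[i]),
            precision=float(precision[i]),
            recall=float(recall[i]),
            f1=float(f1[i]),
        )
        for i in range(c)
    ]
    return per_class, accuracy


def classification_report(y_true, y_pred, class_names: list[str]) -> MetricsReport:
    """Full report: confusion matrix, per-class and averaged metrics."""
    num_classes = len(class_names)
    confusion = confusion_matrix(y_true, y_pred, num_classes)
    per_class, accuracy = per_class_metrics(confusion, class_names)
    support = np.array([c.support for c in per_class], dtype=np.float64)
    total = support.sum()

    def _avg(values: np.ndarray, weights: np.ndarray | None) -> float:
        if weights is None:
            return float(values.mean())
        return float((values * weights).sum() / total)

    prec = np.array([c.precision for c in per_class])
    rec = np.array([c.recall for c in per_class])
    f1 = np.array([c.f1 for c in per_class])
    weighted = {
        "precision": _avg(prec, support),
        "recall": _avg(rec, support),
        "f1": _avg(f1, support),
    }
    macro = {"precision": _avg(prec, None), "recall": _avg(rec, None), "f1": _avg(f1, None)}
    return MetricsReport(
        confusion=confusion,
        per_class=per_class,
        accuracy=accuracy,
        weighted=weighted,
        macro=macro,
        class_names=list(class_names),
    )
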