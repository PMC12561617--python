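"""Classification metrics and the accuracy/latency tradeoff factor.

Multiclass precision, recall/sensitivity, F1 and specificity are computed
one-vs-rest from the confusion matrix and macro-averaged (per-class values
averaged with equal weight); a weighted average is available as an option.
Accuracy is the trace of the confusion matrix over the total count.

The tradeoff factor compares a baseline model b with a compressed model m::

    theta = (Acc_b - Acc_m) - (t_b - t_m)

with accuracies in percent and per-image inference times in milliseconds
subtracted as printed, without unit normalization.  Lower is better: a
compressed model that loses little accuracy while being much faster gets a
negative theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "TradeoffResult",
           "confusion_matrix", "metrics_from_confusion", "evaluate_predictions",
           "tradeoff_factor"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints; rows = true class, cols = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class k."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     num_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    counts = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    per_class: dict = field(default_factory=dict)   # name -> per-class vector
    absent_classes: tuple = ()                      # flagged: no truth & no preds

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "specificity": self.specificity}

    def summary(self) -> str:
        lines = ["metric        macro    " + "  ".join(
            f"class{k}" for k in range(len(self.per_class["precision"])))]
        for name in ("accuracy", "precision", "recall", "f1", "specificity"):
            macro = getattr(self, name)
            if name == "accuracy":
                lines.append(f"{name:<12}  {macro:.4f}")
                continue
            per = "  ".join(f"{v:.4f}" for v in self.per_class[name])
            lines.append(f"{name:<12}  {macro:.4f}   {per}")
        return "\n".join(lines)


def metrics_from_confusion(cm: ConfusionMatrix,
                           average: str = "macro") -> MetricsReport:
    """Per-class one-vs-rest metrics plus their (macro by default) average.

    A class absent from both the truth and the predictions contributes zeros
    and is flagged in ``absent_classes``.
    """
    if average not in ("macro", "weighted"):
        raise ValueError("average must be 'macro' or 'weighted'")
    k = cm.num_classes
    prec = np.zeros(k)
    rec = np.zeros(k)
    f1 = np.zeros(k)
    spec = np.zeros(k)
    support = cm.counts.sum(axis=1).astype(float)
    absent = []
    for i in range(k):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        if tp + fn == 0 and tp + fp == 0:
            absent.append(i)
            continue
        prec[i] = tp / (tp + fp) if tp + fp else 0.0
        rec[i] = tp / (tp + fn) if tp + fn else 0.0
        f1[i] = (2 * prec[i] * rec[i] / (prec[i] + rec[i])
                 if prec[i] + rec[i] else 0.0)
        spec[i] = tn / (tn + fp) if tn + fp else 0.0
    if average == "macro":
        w = np.ones(k) / k
    else:
        w = support / support.sum() if support.sum() else np.ones(k) / k
    return MetricsReport(
        accuracy=float(np.trace(cm.counts)) / cm.total if cm.total else 0.0,
        precision=float(w @ prec), recall=float(w @ rec), f1=float(w @ f1),
        specificity=float(w @ spec),
        per_class={"precision": prec, "recall": rec, "f1": f1, "specificity": spec},
        absent_classes=tuple(absent),
    )


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray, num_classes: int,
                         average: str = "macro") -> tuple[ConfusionMatrix, MetricsReport]:
    cm = confusion_matrix(y_true, y_pred, num_classes)
    return cm, metrics_from_confusion(cm, average=average)


@dataclass
class TradeoffResult:
    theta: float
    acc_baseline: float   # percent
    acc_method: float     # percent
    t_baseline: float     # ms / image
    t_method: float       # ms / image


def tradeoff_factor(acc_b: float, acc_m: float, t_b: float, t_m: float) -> TradeoffResult:
    """theta = (Acc_b - Acc_m) - (t_b - t_m); lower is a better tradeoff."""
    if t_b <= 0 or t_m <= 0:
        raise ValueError("inference times must be positive")
    return TradeoffResult(theta=(acc_b - acc_m) - (t_b - t_m),
                          acc_baseline=acc_b, acc_method=acc_m,
                          t_baseline=t_b, t_method=t_m)
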