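"""Confusion matrices and classification metrics.

Per-class precision TP/(TP+FP), recall TP/(TP+FN) and F1 = 2PR/(P+R)
are computed straight from the confusion matrix; accuracy is
trace/total.  Headline aggregates are support-weighted means; the
micro-average (which for single-label multi-class data collapses to
accuracy) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics"]

N_CLASSES = 5


@dataclass
class ConfusionMatrix:
    """Count grid: rows = true group, cols = predicted group."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    precision_micro: float
    recall_micro: float
    f1_micro: float
    per_class: dict[int, dict[str, float]]
    undefined_classes: list[int] = field(default_factory=list)
    loss: float | None = None


def confusion(y_true, y_pred, n_classes: int = N_CLASSES) -> ConfusionMatrix:
    """Count (true, predicted) pairs into an n_classes x n_classes grid."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.size and (min(yt.min(), yp.min()) < 0 or max(yt.max(), yp.max()) >= n_classes):
        raise ValueError(f"labels must be in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (yt, yp), 1)
    return ConfusionMatrix(cm)


def metrics(cm: ConfusionMatrix, loss: float | None = None) -> MetricsReport:
    """Per-class and aggregated metrics from a confusion matrix.

    A class with no support and no predictions has undefined metrics;
    it is reported as 0 and flagged in ``undefined_classes``.
    """
    c = cm.counts
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = c.shape[0]
    tp = np.diag(c).astype(float)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    support = c.sum(axis=1).astype(float)

    per_class: dict[int, dict[str, float]] = {}
    undefined: list[int] = []
    prec = np.zeros(k)
    rec = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        if support[i] == 0 and tp[i] + fp[i] == 0:
            undefined.append(i)
        prec[i] = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else 0.0
        rec[i] = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
        f1[i] = (2 * prec[i] * rec[i] / (prec[i] + rec[i])
                 if prec[i] + rec[i] > 0 else 0.0)
        per_class[i] = {"precision": prec[i], "recall": rec[i], "f1": f1[i],
                        "support": int(support[i])}

    w = support / support.sum()
    micro_p = tp.sum() / max(tp.sum() + fp.sum(), 1.0)
    micro_r = tp.sum() / max(tp.sum() + fn.sum(), 1.0)
    micro_f = (2 * micro_p * micro_r / (micro_p + micro_r)
               if micro_p + micro_r > 0 else 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision_weighted=float((w * prec).sum()),
        recall_weighted=float((w * rec).sum()),
        f1_weighted=float((w * f1).sum()),
        precision_micro=float(micro_p),
        recall_micro=float(micro_r),
        f1_micro=float(micro_f),
        per_class=per_class,
        undefined_classes=undefined,
        loss=loss,
    )
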