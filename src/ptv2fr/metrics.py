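"""Point-wise segmentation metrics: per-class and macro IoU, precision,
recall and F1 from TP/FP/FN counts.  Points whose true label is -1 are
excluded; classes absent from both prediction and truth are reported as
NaN and excluded from the macro means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cloud import CLASS_NAMES, IGNORE


@dataclass
class ConfusionCounts:
    matrix: np.ndarray    # (C, C): rows true, columns predicted

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix).astype(np.int64)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp


def confusion_counts(pred_labels: np.ndarray, true_labels: np.ndarray,
                     num_classes: int = 3) -> ConfusionCounts:
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have equal length")
    valid = true != IGNORE
    pred, true = pred[valid], true[valid]
    matrix = np.bincount(true * num_classes + pred,
                         minlength=num_classes * num_classes
                         ).reshape(num_classes, num_classes)
    return ConfusionCounts(matrix=matrix)


@dataclass
class MetricReport:
    iou: np.ndarray        # per class, NaN where undefined
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    num_classes: int

    @property
    def mean_iou(self) -> float:
        return float(np.nanmean(self.iou))

    @property
    def mean_precision(self) -> float:
        return float(np.nanmean(self.precision))

    @property
    def mean_recall(self) -> float:
        return float(np.nanmean(self.recall))

    @property
    def mean_f1(self) -> float:
        return float(np.nanmean(self.f1))

    def to_dataframe(self) -> pd.DataFrame:
        rows = {CLASS_NAMES.get(c, str(c)): [self.iou[c], self.precision[c],
                                             self.recall[c], self.f1[c]]
                for c in range(self.num_classes)}
        rows["mean"] = [self.mean_iou, self.mean_precision,
                        self.mean_recall, self.mean_f1]
        return pd.DataFrame(rows, index=["IoU", "Precision", "Recall", "F1"]).T


def metric_report(counts: ConfusionCounts) -> MetricReport:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 their harmonic mean,
    IoU = TP/(TP+FP+FN).  A class with TP+FP+FN = 0 is undefined (NaN);
    P = R = 0 gives F1 = 0."""
    tp = counts.tp.astype(np.float64)
    fp = counts.fp.astype(np.float64)
    fn = counts.fn.astype(np.float64)
    c = len(tp)
    seen = tp + fp + fn > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
        iou = np.where(seen, tp / np.maximum(tp + fp + fn, 1.0), 0.0)
    for arr in (precision, recall, f1, iou):
        arr[~seen] = np.nan
    return MetricReport(iou=iou, precision=precision, recall=recall, f1=f1,
                        num_classes=c)
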