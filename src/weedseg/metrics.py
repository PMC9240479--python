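"""Segmentation evaluation: confusion matrix, per-class IoU, mIoU, mPA.

Definitions (pixel counts, per class i, from a K x K confusion matrix C
with C[i, j] = pixels of true class i predicted as class j):

* TP_i = C[i, i]; FP_i = column i minus TP_i; FN_i = row i minus TP_i.
* IoU_i = TP_i / (TP_i + FP_i + FN_i); a class absent from both
  prediction and truth has an empty union and scores 1.0 by convention
  (configurable: such classes can instead be dropped from the mean).
* mIoU = mean_i IoU_i; mPA = mean_i TP_i / (TP_i + FN_i) (mean per-class
  recall, i.e. mean pixel accuracy of each category).

Both means run over the K = 3 annotated classes (background, soybean,
grass) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MetricsError(ValueError):
    pass


def confusion(pred: np.ndarray, truth: np.ndarray, num_classes: int = 3) -> np.ndarray:
    """Exact per-pixel tally; entry (i, j) = pixels of true i predicted j."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricsError(f"size mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.min(initial=0) < 0 or truth.min(initial=0) < 0 \
            or pred.max(initial=0) >= num_classes or truth.max(initial=0) >= num_classes:
        raise MetricsError(f"mask values must lie in [0, {num_classes})")
    idx = truth.ravel().astype(np.intp) * num_classes + pred.ravel().astype(np.intp)
    return np.bincount(idx, minlength=num_classes * num_classes).reshape(
        num_classes, num_classes)


def iou_per_class(cm: np.ndarray, absent_value: float = 1.0) -> np.ndarray:
    """IoU_i = TP / (TP + FP + FN); empty-union classes get `absent_value`."""
    cm = np.asarray(cm, dtype=np.float64)
    tp = np.diag(cm)
    union = cm.sum(axis=0) + cm.sum(axis=1) - tp
    return np.where(union > 0, np.divide(tp, union, out=np.zeros_like(tp),
                                         where=union > 0), absent_value)


def miou(cm: np.ndarray, include_absent: bool = True) -> float:
    """Mean IoU over classes; absent classes count as 1.0 or are dropped."""
    cm = np.asarray(cm, dtype=np.float64)
    ious = iou_per_class(cm)
    if include_absent:
        return float(ious.mean())
    union = cm.sum(axis=0) + cm.sum(axis=1) - np.diag(cm)
    present = union > 0
    return float(ious[present].mean()) if present.any() else 1.0


def mpa(cm: np.ndarray) -> float:
    """Mean per-class pixel accuracy (recall); truth-absent classes count 1.0."""
    cm = np.asarray(cm, dtype=np.float64)
    tp = np.diag(cm)
    support = cm.sum(axis=1)
    acc = np.where(support > 0, np.divide(tp, support, out=np.zeros_like(tp),
                                          where=support > 0), 1.0)
    return float(acc.mean())


def pixel_accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=np.float64)
    return float(np.diag(cm).sum() / cm.sum())


@dataclass
class MetricsReport:
    per_class_iou: list
    miou: float
    mpa: float
    pixel_accuracy: float
    confusion: list

    def as_dict(self):
        return {
            "per_class_iou": self.per_class_iou,
            "miou": self.miou,
            "mpa": self.mpa,
            "pixel_accuracy": self.pixel_accuracy,
        }


def evaluate(preds, truths, num_classes: int = 3) -> MetricsReport:
    """Aggregate a confusion matrix over (pred, truth) mask pairs and report."""
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    for p, t in zip(preds, truths):
        cm += confusion(p, t, num_classes)
    return MetricsReport(
        per_class_iou=[float(v) for v in iou_per_class(cm)],
        miou=miou(cm),
        mpa=mpa(cm),
        pixel_accuracy=pixel_accuracy(cm),
        confusion=cm.tolist(),
    )
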