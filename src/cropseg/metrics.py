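"""Confusion-matrix evaluation: overall accuracy, average accuracy, mIoU.

Rows of the confusion matrix are truth, columns are prediction; ignored
pixels are never counted.  OA is the fraction of pixels on the diagonal,
AA the mean per-class recall, mIoU the mean per-class intersection over
union — all reported as percentages.  Classes with no true pixels are
dropped from AA; classes absent from both truth and prediction are dropped
from mIoU (avoids 0/0 in sparse folds).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd


@dataclasses.dataclass
class MetricsReport:
    confusion: np.ndarray
    oa: float
    aa: float
    miou: float
    per_class_recall: np.ndarray
    per_class_iou: np.ndarray

    def to_dict(self) -> dict:
        return {
            "oa": self.oa, "aa": self.aa, "miou": self.miou,
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_iou": self.per_class_iou.tolist(),
            "confusion": self.confusion.tolist(),
        }

    def save(self, path_json, path_csv=None, class_names=None) -> None:
        pathlib.Path(path_json).write_text(json.dumps(self.to_dict(), indent=2))
        if path_csv is not None:
            c = self.confusion.shape[0]
            names = list(class_names) if class_names else [f"class_{i}" for i in range(c)]
            pd.DataFrame({
                "class": names,
                "recall_pct": self.per_class_recall,
                "iou_pct": self.per_class_iou,
            }).to_csv(path_csv, index=False)


def accumulate(pred: np.ndarray, truth: np.ndarray, ignore: int = 255,
               confusion: np.ndarray | None = None, n_classes: int = 4) -> np.ndarray:
    """Add per-pixel counts of one prediction/truth pair to a confusion matrix."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if confusion is None:
        confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    c = confusion.shape[0]
    keep = truth != ignore
    t = truth[keep].astype(np.int64)
    p = pred[keep].astype(np.int64)
    confusion += np.bincount(t * c + p, minlength=c * c).reshape(c, c)
    return confusion


def summarize(confusion: np.ndarray) -> MetricsReport:
    """Derive OA/AA/mIoU (in percent) from an accumulated confusion matrix."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(confusion).astype(float)
    row = confusion.sum(axis=1).astype(float)   # true support
    col = confusion.sum(axis=0).astype(float)   # predicted support
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        iou_den = row + col - diag
        iou = np.where(iou_den > 0, diag / iou_den, np.nan)
    oa = 100.0 * diag.sum() / total
    aa = 100.0 * np.nanmean(recall)
    miou = 100.0 * np.nanmean(iou)
    return MetricsReport(
        confusion=confusion.copy(),
        oa=float(oa), aa=float(aa), miou=float(miou),
        per_class_recall=100.0 * recall,
        per_class_iou=100.0 * iou,
    )


def overall_accuracy(pred: np.ndarray, truth: np.ndarray, ignore: int = 255) -> float:
    """Convenience OA (percent) for a single prediction/truth pair."""
    keep = np.asarray(truth) != ignore
    if not keep.any():
        raise ValueError("no valid pixels")
    return 100.0 * float(np.mean(np.asarray(pred)[keep] == np.asarray(truth)[keep]))
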