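"""Segmentation metrics restricted to the field of view."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "confusion_metrics", "roc_auc", "dice"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_shapes(*imgs):
    shapes = {i.shape for i in imgs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {shapes}")


def confusion_metrics(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray):
    """(ConfusionCounts, Se, Sp, Acc) over FOV pixels only.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/all; any nonzero truth
    pixel counts as vessel (mask encodings vary between datasets).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth) != 0
    fov = np.asarray(fov).astype(bool)
    _check_shapes(pred, truth, fov)
    p = pred[fov]
    t = truth[fov]
    counts = ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)), fn=int(np.sum(~p & t)))

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    se = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    sp = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    acc = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    return counts, se, sp, acc


def roc_auc(vmap: np.ndarray, truth: np.ndarray, fov: np.ndarray) -> float:
    """Area under the ROC curve of the vesselness score within the FOV."""
    vmap = np.asarray(vmap, float)
    truth = np.asarray(truth) != 0
    fov = np.asarray(fov).astype(bool)
    _check_shapes(vmap, truth, fov)
    t = truth[fov]
    if t.all() or not t.any():
        raise ValueError("both classes must be present inside the FOV")
    return float(roc_auc_score(t, vmap[fov]))


def dice(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|), optionally restricted to the FOV."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth) != 0
    if fov is not None:
        fov = fov.astype(bool)
        pred = pred & fov
        truth = truth & fov
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(pred & truth) / denom)
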