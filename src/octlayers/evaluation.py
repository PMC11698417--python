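"""Segmentation metrics and layer-topology diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "dice_iou", "column_topology_violations"]


@dataclass
class MetricReport:
    """Per-class and aggregate overlap metrics.

    ``mean_dice``/``mean_iou`` aggregate over tissue classes (background
    excluded unless the report was built with include_background).  A
    class absent from both prediction and truth scores 1 by convention so
    small-set means stay defined.
    """

    dice: np.ndarray          # (K,)
    iou: np.ndarray           # (K,)
    mean_dice: float
    mean_iou: float
    include_background: bool = False

    def to_frame(self) -> pd.DataFrame:
        k = len(self.dice)
        df = pd.DataFrame({"class": np.arange(k), "dice": self.dice,
                           "iou": self.iou})
        return df


def dice_iou(pred_mask: np.ndarray, truth: np.ndarray, K: int,
             include_background: bool = False) -> MetricReport:
    """Per-class Dice = 2|P∩T|/(|P|+|T|) and IoU = |P∩T|/|P∪T|.

    Symmetric in (pred, truth).  Means are over classes 1..K-1 unless
    ``include_background``.
    """
    pred_mask = np.asarray(pred_mask)
    truth = np.asarray(truth)
    if pred_mask.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if pred_mask.max(initial=0) >= K or truth.max(initial=0) >= K:
        raise ValueError(f"labels must be < K={K}")
    dice = np.empty(K)
    iou = np.empty(K)
    for k in range(K):
        p = pred_mask == k
        t = truth == k
        inter = np.logical_and(p, t).sum()
        psum, tsum = p.sum(), t.sum()
        if psum + tsum == 0:
            dice[k] = iou[k] = 1.0
        else:
            dice[k] = 2.0 * inter / (psum + tsum)
            union = psum + tsum - inter
            iou[k] = inter / union if union else 1.0
    sel = slice(None) if include_background else slice(1, None)
    return MetricReport(dice=dice, iou=iou,
                        mean_dice=float(dice[sel].mean()),
                        mean_iou=float(iou[sel].mean()),
                        include_background=include_background)


def column_topology_violations(mask: np.ndarray) -> float:
    """Fraction of columns whose top-to-bottom class sequence breaks the
    ordered-layer grammar.

    A valid column reads: a background run, then runs of strictly
    increasing tissue indices, then optionally one final background run
    (each class at most once).  An all-background column is valid.
    """
    mask = np.asarray(mask).astype(np.int64)  # unsigned dtypes wrap in diff
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    h, w = mask.shape
    bad = 0
    for c in range(w):
        col = mask[:, c]
        change = np.flatnonzero(np.diff(col)) + 1
        runs = col[np.concatenate(([0], change))]
        if runs[0] != 0:
            bad += 1
            continue
        tissue = runs[1:]
        if len(tissue) and tissue[-1] == 0:
            tissue = tissue[:-1]
        if (tissue == 0).any() or not (np.diff(tissue) > 0).all():
            bad += 1
    return bad / w
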