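"""Pixel-level agreement metrics between predicted and true ROI masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dataio import ROIMask


@dataclass(frozen=True)
class SegMetrics:
    pixel_accuracy: float
    dice: float
    roi_sensitivity: float
    roi_specificity: float


def evaluate_masks(pred: ROIMask, truth: ROIMask) -> SegMetrics:
    """Pixel accuracy, Dice, and ROI sensitivity/specificity.

    Empty-set conventions: if both masks are empty, dice and sensitivity
    are 1; if only the truth is empty they are 0.  Specificity is treated
    symmetrically over the complement.
    """
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    p = pred.mask
    t = truth.mask
    inter = int((p & t).sum())
    psum = int(p.sum())
    tsum = int(t.sum())
    acc = float((p == t).mean())
    if psum + tsum == 0:
        dice = 1.0
    else:
        dice = 2.0 * inter / (psum + tsum)
    if tsum == 0:
        sens = 1.0 if psum == 0 else 0.0
    else:
        sens = inter / tsum
    n_neg = t.size - tsum
    if n_neg == 0:
        spec = 1.0 if psum == p.size else 0.0
    else:
        spec = int((~p & ~t).sum()) / n_neg
    return SegMetrics(acc, dice, sens, spec)
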