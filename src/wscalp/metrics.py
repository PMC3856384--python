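"""Overlap scores between a predicted mask and a ground-truth mask."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Mask


@dataclass(frozen=True)
class OverlapScores:
    """Dice, Jaccard, sensitivity and specificity, all in [0, 1].

    Jaccard and Dice are redundant (jaccard = dice / (2 - dice)); both are
    reported because both are standard.
    """

    dice: float
    jaccard: float
    sensitivity: float
    specificity: float


def overlap(pred: Mask, truth: Mask) -> OverlapScores:
    """Voxel-count overlap scores of ``pred`` against ``truth``.

    Specificity is computed over the grid complement of the truth mask.
    Raises if both masks are empty (every score would be 0/0).
    """
    if not pred.same_grid(truth):
        raise ValueError("overlap: masks are on different grids")
    a = pred.data
    b = truth.data
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("overlap: both masks are empty")
    inter = int((a & b).sum())
    union = na + nb - inter
    dice = 2.0 * inter / (na + nb)
    jaccard = inter / union if union else 1.0
    sensitivity = inter / nb if nb else 0.0
    neg = a.size - nb
    tn = int((~a & ~b).sum())
    specificity = tn / neg if neg else 1.0
    return OverlapScores(dice, jaccard, sensitivity, specificity)
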