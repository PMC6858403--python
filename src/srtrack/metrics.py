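"""Overlap metrics for scoring predicted against ground-truth masks."""

from __future__ import annotations

import numpy as np

__all__ = ["overlap_index", "dice"]


def _as_masks(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    if not pred.any() and not gt.any():
        raise ValueError("overlap of two empty masks is undefined")
    return pred, gt


def overlap_index(pred, gt) -> float:
    """Jaccard overlap as a percentage: 100 * |pred & gt| / |pred | gt|."""
    pred, gt = _as_masks(pred, gt)
    inter = np.count_nonzero(pred & gt)
    union = np.count_nonzero(pred | gt)
    return 100.0 * inter / union


def dice(pred, gt) -> float:
    """Dice coefficient: 2|X & Y| / (|X| + |Y|)."""
    pred, gt = _as_masks(pred, gt)
    inter = np.count_nonzero(pred & gt)
    return 2.0 * inter / (np.count_nonzero(pred) + np.count_nonzero(gt))
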