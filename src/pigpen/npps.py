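"""Non-pig pixel suppression (NPPS): per-pixel adaptive thresholding.

A single global threshold on the difference image cannot cope with spatially
varying lighting, so NPPS keeps an individual threshold per pixel.  All
thresholds start at the Otsu value of the first difference image, then drift
by one level per frame, steered by the detection boxes: inside a box a
threshold above the local difference drops (letting animal pixels through),
outside the boxes a threshold below the local difference rises (suppressing
background flicker).  Thresholds are clamped to [min_thresh, max_thresh].
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .frames import Box, boxes_mask

__all__ = ["ThresholdMap", "otsu_threshold", "init_thresholds",
           "update_thresholds", "foreground_mask"]

DEFAULT_MIN_THRESH = 10
DEFAULT_MAX_THRESH = 245


@dataclasses.dataclass
class ThresholdMap:
    thresholds: np.ndarray  # int16 (H, W)
    min_thresh: int = DEFAULT_MIN_THRESH
    max_thresh: int = DEFAULT_MAX_THRESH


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram.

    Returns the t in [0, 254] maximizing the between-class variance of the
    split into classes <= t and > t; ties break toward the smallest t, and a
    uniform image yields 0.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    hist = np.bincount(image.ravel().astype(np.int64), minlength=256).astype(np.float64)
    n = hist.sum()
    p = hist / n
    omega = np.cumsum(p)[:255]            # weight of class <= t
    mu = np.cumsum(p * np.arange(256))[:255]  # first moment of class <= t
    mu_total = (p * np.arange(256)).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -1.0)
    best = sigma_b.max()
    if best <= 0:  # uniform image: every split is degenerate
        return 0
    return int(np.argmax(sigma_b))  # argmax returns the smallest maximizer


def init_thresholds(
    first_diff: np.ndarray,
    min_thresh: int = DEFAULT_MIN_THRESH,
    max_thresh: int = DEFAULT_MAX_THRESH,
) -> ThresholdMap:
    """Broadcast the Otsu threshold of the first difference image, clamped."""
    t = int(np.clip(otsu_threshold(first_diff), min_thresh, max_thresh))
    first_diff = np.asarray(first_diff)
    return ThresholdMap(
        thresholds=np.full(first_diff.shape, t, dtype=np.int16),
        min_thresh=min_thresh,
        max_thresh=max_thresh,
    )


def update_thresholds(
    tmap: ThresholdMap, diff: np.ndarray, boxes: Sequence[Box] = ()
) -> ThresholdMap:
    """One +/-1 adaptation step of the per-pixel thresholds (in place)."""
    diff = np.asarray(diff, dtype=np.int16)
    if diff.shape != tmap.thresholds.shape:
        raise ValueError("difference/threshold-map dimension mismatch")
    in_box = boxes_mask(boxes, diff.shape[1], diff.shape[0])
    t = tmap.thresholds
    t -= (in_box & (t > diff)).astype(np.int16)
    t += (~in_box & (t < diff)).astype(np.int16)
    np.clip(t, tmap.min_thresh, tmap.max_thresh, out=t)
    return tmap


def foreground_mask(diff: np.ndarray, tmap: ThresholdMap) -> np.ndarray:
    """255 where the difference strictly exceeds its pixel threshold, else 0."""
    diff = np.asarray(diff, dtype=np.int16)
    if diff.shape != tmap.thresholds.shape:
        raise ValueError("difference/threshold-map dimension mismatch")
    return np.where(diff > tmap.thresholds, 255, 0).astype(np.uint8)
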