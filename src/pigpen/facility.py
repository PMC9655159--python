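"""Streaming occlusion ("facility") map estimation.

Fixed pen structures — feeders, pipes, walls — occlude the animals, so no
animal pixel is ever observed there.  The facility image F starts saturated
at 255 and is decremented wherever animal evidence appears: inside a
retained detection box, at pixels whose difference-image value exceeds the
box's mean difference.  Boxes whose mean difference falls below the global
mean are treated as suspected false positives and skipped.

Because the difference image is noisy, F is periodically calibrated: pixels
still above a noise ceiling (default 245) are snapped back to 255 together
with their immediate 8-connected neighbors, erasing sparse noise hits.
Saturated pixels after calibration mark the occluded regions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import scipy.ndimage

from .frames import Box

__all__ = ["FacilityState", "init_facility", "update_facility",
           "calibrate_facility", "facility_mask"]


@dataclasses.dataclass
class FacilityState:
    facility: np.ndarray  # uint8 (H, W), init 255
    frames_since_calibration: int = 0
    calibration_interval: int = 10_000
    noise_ceiling: int = 245
    cutoff: int = 255
    calibrations_done: int = 0


def init_facility(
    width: int,
    height: int,
    calibration_interval: int = 10_000,
    noise_ceiling: int = 245,
    cutoff: int = 255,
) -> FacilityState:
    """All-255 facility image with zeroed counters."""
    if width <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    return FacilityState(
        facility=np.full((height, width), 255, dtype=np.uint8),
        calibration_interval=calibration_interval,
        noise_ceiling=noise_ceiling,
        cutoff=cutoff,
    )


def update_facility(
    state: FacilityState, diff: np.ndarray, boxes: Sequence[Box] = ()
) -> tuple[FacilityState, np.ndarray]:
    """One streaming update; returns the state and the pig-region mask.

    A box is retained only if its mean difference is at least the global
    mean difference (animal regions differ from the background more than the
    scene at large; weaker boxes are suspected false positives).  Within a
    retained box, pixels whose difference exceeds the box mean are marked as
    pig region (mask 255) and have their facility value decremented by 1
    (clamped at 0).  Calibration fires automatically every
    ``calibration_interval`` updates.
    """
    diff = np.asarray(diff, dtype=np.uint8)
    if diff.shape != state.facility.shape:
        raise ValueError("difference/facility dimension mismatch")
    h, w = diff.shape
    global_mean = float(diff.mean())
    pig_mask = np.zeros_like(diff)
    f = state.facility.astype(np.int16)
    for b in boxes:
        x0 = max(0, int(np.floor(b.x_min)))
        y0 = max(0, int(np.floor(b.y_min)))
        x1 = min(w, int(np.ceil(b.x_max)))
        y1 = min(h, int(np.ceil(b.y_max)))
        if x1 <= x0 or y1 <= y0:
            continue
        region = diff[y0:y1, x0:x1]
        box_mean = float(region.mean())
        if box_mean < global_mean:
            continue  # suspected false positive
        hit = region > box_mean
        pig_mask[y0:y1, x0:x1][hit] = 255
        sub = f[y0:y1, x0:x1]
        sub[hit] = np.maximum(sub[hit] - 1, 0)
    state.facility = f.astype(np.uint8)
    state.frames_since_calibration += 1
    if state.frames_since_calibration >= state.calibration_interval:
        calibrate_facility(state)
    return state, pig_mask


def calibrate_facility(state: FacilityState, neighbor_radius: int = 1) -> FacilityState:
    """Snap near-saturated pixels (and their neighbors) back to 255.

    Every pixel strictly above ``noise_ceiling`` is reset to 255, along with
    its 8-connected neighborhood (radius configurable).  Resets the
    calibration counter.
    """
    high = state.facility > state.noise_ceiling
    if neighbor_radius > 0 and high.any():
        size = 2 * neighbor_radius + 1
        high = scipy.ndimage.binary_dilation(high, np.ones((size, size), bool))
    f = state.facility.copy()
    f[high] = 255
    state.facility = f
    state.frames_since_calibration = 0
    state.calibrations_done += 1
    return state


def facility_mask(state: FacilityState) -> np.ndarray:
    """Binary occlusion mask: 255 where facility >= cutoff, else 0."""
    if state.calibrations_done == 0:
        warnings.warn(
            "facility mask requested before any calibration; result may "
            "contain uncalibrated noise",
            stacklevel=2,
        )
    return np.where(state.facility >= state.cutoff, 255, 0).astype(np.uint8)
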