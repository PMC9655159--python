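"""Streaming pixel-level background estimation from detections.

The background image B is a running per-pixel estimate of the animal-free
scene.  Each frame, every pixel *outside* all detection boxes steps toward
the current frame by exactly one intensity level (a signed running-median
style update); pixels inside boxes are held, so animals never bleed into the
estimate.  The per-step bound of 1 makes the estimator robust to transient
noise while converging to any static scene within 255 updates.

The companion difference image |frame - B| feeds the facility and
foreground-segmentation stages.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .frames import Box, boxes_mask

__all__ = ["BackgroundState", "init_background", "update_background",
           "difference_image"]


@dataclasses.dataclass
class BackgroundState:
    background: np.ndarray  # uint8 (H, W)
    frames_seen: int = 1
    # compare: 'background' steps B toward the current frame (default);
    # 'prev_frame' steps B by the sign of frame_t - frame_{t-1} instead.
    compare: str = "background"
    # box_mode: 'hold' freezes B inside boxes; 'frame_mean' overwrites box
    # pixels with the current frame's mean intensity.
    box_mode: str = "hold"
    prev_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.compare not in ("background", "prev_frame"):
            raise ValueError(f"unknown compare mode: {self.compare}")
        if self.box_mode not in ("hold", "frame_mean"):
            raise ValueError(f"unknown box mode: {self.box_mode}")


def init_background(
    first_frame: np.ndarray, compare: str = "background", box_mode: str = "hold"
) -> BackgroundState:
    """Start the estimator from a copy of the first frame."""
    first_frame = np.asarray(first_frame)
    if first_frame.ndim != 2:
        raise ValueError("background operates on gray frames")
    return BackgroundState(
        background=first_frame.astype(np.uint8).copy(),
        frames_seen=1,
        compare=compare,
        box_mode=box_mode,
        prev_frame=first_frame.astype(np.uint8).copy(),
    )


def update_background(
    state: BackgroundState, frame: np.ndarray, boxes: Sequence[Box] = ()
) -> BackgroundState:
    """One streaming update of the background estimate (in place).

    Outside all boxes each background pixel moves by +1/-1 toward the
    reference (the current frame by default), and is unchanged on ties.
    Inside boxes the pixel is held, or replaced by the frame's rounded mean
    intensity in ``frame_mean`` mode.
    """
    frame = np.asarray(frame, dtype=np.uint8)
    if frame.shape != state.background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background {state.background.shape}"
        )
    b = state.background.astype(np.int16)
    ref = b if state.compare == "background" else state.prev_frame.astype(np.int16)
    step = np.sign(frame.astype(np.int16) - ref).astype(np.int16)
    in_box = boxes_mask(boxes, frame.shape[1], frame.shape[0])
    step[in_box] = 0
    b = np.clip(b + step, 0, 255)
    if state.box_mode == "frame_mean" and in_box.any():
        b[in_box] = int(np.floor(frame.mean() + 0.5))
    state.background = b.astype(np.uint8)
    state.prev_frame = frame.copy()
    state.frames_seen += 1
    return state


def difference_image(frame: np.ndarray, state: BackgroundState) -> np.ndarray:
    """Per-pixel absolute difference |frame - background|, uint8."""
    frame = np.asarray(frame, dtype=np.uint8)
    if frame.shape != state.background.shape:
        raise ValueError("frame/background dimension mismatch")
    a = frame.astype(np.int16)
    b = state.background.astype(np.int16)
    return np.abs(a - b).astype(np.uint8)
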