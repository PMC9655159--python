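"""Raster frames, detection boxes, and the file formats they travel in.

Frames are plain ``numpy`` arrays: ``uint8`` of shape ``(H, W)`` for gray
frames and ``(H, W, 3)`` for color frames, origin at the top-left corner,
x growing rightward and y downward.  Boxes use 0-based, half-open pixel
intervals ``[x_min, x_max) x [y_min, y_max)``.

Box files follow the YOLO text dialect: one box per line,
``label cx cy w h [confidence]`` with all spatial values normalized to
``[0, 1]`` relative to the frame size.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import skimage.transform

__all__ = [
    "Box",
    "to_grayscale",
    "resize_frame",
    "read_frames",
    "count_frames",
    "write_frame",
    "read_frame",
    "read_boxes",
    "write_boxes",
    "boxes_mask",
    "nms",
    "box_iou",
]

_IMAGE_SUFFIXES = {".png", ".pgm", ".ppm", ".bmp", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclasses.dataclass(frozen=True)
class Box:
    """Axis-aligned detection box in pixel coordinates.

    Coordinates are 0-based and half-open: a full ``W x H`` frame is covered
    by ``Box(0, 0, W, H)``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0
    label: int = 0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence outside [0, 1]: {self.confidence}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def clip(self, width: int, height: int) -> "Box":
        """Clip to the frame; raises ValueError if nothing remains."""
        return Box(
            max(0.0, self.x_min),
            max(0.0, self.y_min),
            min(float(width), self.x_max),
            min(float(height), self.y_max),
            self.confidence,
            self.label,
        )


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim not in (2, 3) or (frame.ndim == 3 and frame.shape[2] != 3):
        raise ValueError(f"expected (H, W) or (H, W, 3) array, got {frame.shape}")
    if frame.shape[0] < 1 or frame.shape[1] < 1:
        raise ValueError("empty frame")
    return frame


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert a color frame to gray via the BT.601 luma weights.

    ``Y = 0.299 R + 0.587 G + 0.114 B``, rounded half-up to the nearest
    integer and clamped to [0, 255].  Gray input is returned unchanged.
    """
    frame = _validate_frame(frame)
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    planes = frame.astype(np.float64)
    luma = 0.299 * planes[..., 0] + 0.587 * planes[..., 1] + 0.114 * planes[..., 2]
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def resize_frame(frame: np.ndarray, target_w: int, target_h: int) -> np.ndarray:
    """Bilinear resize to exactly ``target_w x target_h``."""
    frame = _validate_frame(frame)
    if target_w <= 0 or target_h <= 0:
        raise ValueError("target dimensions must be positive")
    if frame.shape[0] == target_h and frame.shape[1] == target_w:
        return frame.copy()
    out_shape = (target_h, target_w) + frame.shape[2:]
    out = skimage.transform.resize(
        frame, out_shape, order=1, preserve_range=True, anti_aliasing=False
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def _frame_paths(directory: Path) -> list[Path]:
    return sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )


def read_frame(path: str | Path, as_gray: bool = False) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    img = img.astype(np.uint8, copy=False)
    return to_grayscale(img) if as_gray else img


def write_frame(frame: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, _validate_frame(frame))


def read_frames(source: str | Path, as_gray: bool = False) -> Iterator[np.ndarray]:
    """Yield frames in temporal order from a video file or image directory.

    Directory sources are read in lexicographic file-name order; all frames
    must share dimensions.
    """
    source = Path(source)
    if source.is_dir():
        paths = _frame_paths(source)
        if not paths:
            raise ValueError(f"no image files in {source}")
        shape = None
        for p in paths:
            frame = read_frame(p, as_gray=as_gray)
            if shape is None:
                shape = frame.shape[:2]
            elif frame.shape[:2] != shape:
                raise ValueError(
                    f"mixed frame dimensions in {source}: {shape} vs "
                    f"{frame.shape[:2]} ({p.name})"
                )
            yield frame
    elif source.is_file():
        for frame in iio.imiter(source):
            frame = np.asarray(frame)
            if frame.ndim == 3 and frame.shape[2] == 4:
                frame = frame[..., :3]
            frame = frame.astype(np.uint8, copy=False)
            yield to_grayscale(frame) if as_gray else frame
    else:
        raise ValueError(f"unreadable frame source: {source}")


def count_frames(source: str | Path) -> int:
    source = Path(source)
    if source.is_dir():
        return len(_frame_paths(source))
    return sum(1 for _ in read_frames(source))


def read_boxes(path: str | Path, frame_w: int, frame_h: int) -> list[Box]:
    """Read a YOLO text file into absolute half-open pixel boxes."""
    boxes: list[Box] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        label = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else 1.0
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{lineno}: normalized value outside [0,1]: {v}")
        boxes.append(
            Box(
                (cx - w / 2) * frame_w,
                (cy - h / 2) * frame_h,
                (cx + w / 2) * frame_w,
                (cy + h / 2) * frame_h,
                conf,
                label,
            )
        )
    return boxes


def write_boxes(
    boxes: Sequence[Box], path: str | Path, frame_w: int, frame_h: int
) -> None:
    """Write boxes as normalized YOLO text, one line per box."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for b in boxes:
        cx = (b.x_min + b.x_max) / 2 / frame_w
        cy = (b.y_min + b.y_max) / 2 / frame_h
        w = (b.x_max - b.x_min) / frame_w
        h = (b.y_max - b.y_min) / frame_h
        lines.append(f"{b.label} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f} {b.confidence:.6f}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def boxes_mask(boxes: Iterable[Box], width: int, height: int) -> np.ndarray:
    """Boolean mask of all pixels covered by any box (rounded to whole pixels)."""
    mask = np.zeros((height, width), dtype=bool)
    for b in boxes:
        x0 = max(0, int(math.floor(b.x_min)))
        y0 = max(0, int(math.floor(b.y_min)))
        x1 = min(width, int(math.ceil(b.x_max)))
        y1 = min(height, int(math.ceil(b.y_max)))
        if x1 > x0 and y1 > y0:
            mask[y0:y1, x0:x1] = True
    return mask


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes on pixel areas; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(boxes: Sequence[Box], iou_threshold: float) -> list[Box]:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-confidence remaining box and removes every
    box overlapping it with IoU strictly above the threshold.  Ties on
    confidence keep the earlier box first (stable).  Output is sorted by
    confidence descending.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in [0, 1]")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept: list[Box] = []
    suppressed = [False] * len(boxes)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(boxes[i])
        for j in order:
            if not suppressed[j] and j != i and box_iou(boxes[i], boxes[j]) > iou_threshold:
                suppressed[j] = True
    return kept
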