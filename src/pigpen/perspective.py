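"""Perspective normalization for oblique static-camera views.

A camera mounted obliquely over a pen makes animals near the far wall appear
much smaller than animals near the camera.  A projective warp that maps a
user-chosen quadrilateral on the floor plane to an upright rectangle
equalizes apparent size across depth.

The quadrilateral is extended automatically: the lines through its left and
right sides are intersected with the top and bottom frame edges, the frame
is padded horizontally wherever an intersection falls outside it, and the
four intersection points anchor the homography onto the output rectangle.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import skimage.transform

from .frames import Box

__all__ = ["WarpQuad", "WarpSpec", "extend_side_lines", "fit_transform",
           "build_warp", "warp_frame", "map_box"]

Point = tuple[float, float]


@dataclasses.dataclass(frozen=True)
class WarpQuad:
    """Four points marking the warp lines: TL, TR, BR, BL (pixel coords)."""

    top_left: Point
    top_right: Point
    bottom_right: Point
    bottom_left: Point

    def __post_init__(self) -> None:
        pts = np.array(self.points, dtype=float)
        # simple-quad check: consecutive edge cross products must not all vanish
        for i in range(4):
            a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
            ab, ac = b - a, c - a
            if abs(ab[0] * ac[1] - ab[1] * ac[0]) < 1e-9:
                raise ValueError("quad has three collinear points")

    @property
    def points(self) -> tuple[Point, Point, Point, Point]:
        return (self.top_left, self.top_right, self.bottom_right, self.bottom_left)


@dataclasses.dataclass(frozen=True)
class WarpSpec:
    """A fitted projective warp.

    ``matrix`` maps homogeneous source coordinates (in the *padded* plane,
    i.e. original x plus ``pad``) to destination coordinates.  ``points``
    are the eight anchor points in original frame coordinates.
    """

    matrix: np.ndarray  # 3x3, maps padded-source (x, y) -> dst (x, y)
    dst_w: int
    dst_h: int
    pad: float = 0.0
    points: tuple[Point, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("warp matrix must be an invertible 3x3 matrix")
        object.__setattr__(self, "matrix", m)


def _line_x_at(p: Point, q: Point, y: float) -> float:
    """x coordinate where the line through p and q crosses height y."""
    (x1, y1), (x2, y2) = p, q
    if abs(y2 - y1) < 1e-12:
        raise ValueError("side line is horizontal; cannot intersect top/bottom edges")
    return x1 + (y - y1) * (x2 - x1) / (y2 - y1)


def extend_side_lines(
    quad: WarpQuad, frame_w: int, frame_h: int
) -> tuple[tuple[Point, ...], float]:
    """Extend the quad's side lines to the frame's top and bottom edges.

    Returns the eight anchor points (the four quad points followed by the
    four edge intersections: left-top, left-bottom, right-top, right-bottom)
    and the symmetric horizontal padding needed so every intersection lies
    in the padded plane ``[-pad, frame_w + pad)``.
    """
    lt = (_line_x_at(quad.top_left, quad.bottom_left, 0.0), 0.0)
    lb = (_line_x_at(quad.top_left, quad.bottom_left, float(frame_h)), float(frame_h))
    rt = (_line_x_at(quad.top_right, quad.bottom_right, 0.0), 0.0)
    rb = (_line_x_at(quad.top_right, quad.bottom_right, float(frame_h)), float(frame_h))
    xs = [p[0] for p in (lt, lb, rt, rb)]
    pad = max(0.0, -min(xs), max(xs) - frame_w)
    return quad.points + (lt, lb, rt, rb), pad


def fit_transform(src_corners: Sequence[Point], dst_w: int, dst_h: int) -> np.ndarray:
    """Exact homography mapping four source corners onto a dst rectangle.

    Corners are given in TL, TR, BR, BL order and map to
    ``(0,0), (dst_w,0), (dst_w,dst_h), (0,dst_h)``.  Solved as the standard
    8x8 direct linear system; the matrix is normalized so ``H[2,2] = 1``.
    """
    if len(src_corners) != 4:
        raise ValueError("need exactly four source corners")
    dst = [(0.0, 0.0), (float(dst_w), 0.0), (float(dst_w), float(dst_h)),
           (0.0, float(dst_h))]
    a = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src_corners, dst)):
        a[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        a[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i] = u
        b[2 * i + 1] = v
    try:
        h = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate source corners (singular system)") from exc
    return np.array([[h[0], h[1], h[2]], [h[3], h[4], h[5]], [h[6], h[7], 1.0]])


def build_warp(
    quad: WarpQuad, frame_w: int, frame_h: int, dst_w: int = 512, dst_h: int = 288
) -> WarpSpec:
    """Full automatic warp: extend the quad's sides, pad, fit the homography.

    The four edge-intersection points (in padded-plane coordinates) anchor
    the homography onto the corners of the ``dst_w x dst_h`` rectangle.
    """
    points, pad = extend_side_lines(quad, frame_w, frame_h)
    _, _, _, _, lt, lb, rt, rb = points
    src = [(lt[0] + pad, lt[1]), (rt[0] + pad, rt[1]),
           (rb[0] + pad, rb[1]), (lb[0] + pad, lb[1])]
    matrix = fit_transform(src, dst_w, dst_h)
    return WarpSpec(matrix=matrix, dst_w=dst_w, dst_h=dst_h, pad=pad, points=points)


def warp_frame(frame: np.ndarray, spec: WarpSpec, order: int = 1) -> np.ndarray:
    """Apply the warp; bilinear sampling, out-of-source pixels filled with 0.

    The frame is zero-padded horizontally by ``spec.pad`` on each side before
    warping, matching the padded source plane the matrix was fitted in.
    """
    pad = int(np.ceil(spec.pad))
    if pad > 0:
        pad_width = ((0, 0), (pad, pad)) + ((0, 0),) * (frame.ndim - 2)
        frame = np.pad(frame, pad_width, mode="constant")
    tform = skimage.transform.ProjectiveTransform(matrix=spec.matrix)
    out_shape = (spec.dst_h, spec.dst_w) + frame.shape[2:]
    out = skimage.transform.warp(
        frame.astype(np.float64), tform.inverse, output_shape=out_shape,
        order=order, cval=0.0, preserve_range=True,
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def map_box(box: Box, spec: WarpSpec, direction: str = "forward") -> Box:
    """Map a box through the warp (or its inverse).

    The four corners are projected; the result is their axis-aligned
    bounding box clipped to the destination (forward) or padded-source
    (inverse) frame.  Forward mapping treats input coordinates as original
    frame coordinates (the pad offset is applied internally).
    """
    if direction not in ("forward", "inverse"):
        raise ValueError(f"unknown direction: {direction}")
    m = spec.matrix if direction == "forward" else np.linalg.inv(spec.matrix)
    offset = spec.pad if direction == "forward" else 0.0
    corners = np.array([
        [box.x_min + offset, box.y_min, 1.0],
        [box.x_max + offset, box.y_min, 1.0],
        [box.x_max + offset, box.y_max, 1.0],
        [box.x_min + offset, box.y_max, 1.0],
    ])
    proj = corners @ m.T
    proj = proj[:, :2] / proj[:, 2:3]
    if direction == "inverse":
        proj[:, 0] -= spec.pad
    out = Box(proj[:, 0].min(), proj[:, 1].min(), proj[:, 0].max(), proj[:, 1].max(),
              box.confidence, box.label)
    if direction == "forward":
        return out.clip(spec.dst_w, spec.dst_h)
    return out
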