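"""Synthetic pen scenes with ground truth, and a fallible oracle detector.

The generator emulates what a static camera over a livestock pen records:
a textured static floor, static occluding structures (feeder, pipe) drawn
*on top* of the animals, several elliptical animals of differing intensity
patrolling the pen, and additive Gaussian pixel noise.  Every frame comes
with its ground truth: the animal-free background, the occluder mask, each
animal's full and visible masks, and tight boxes around the visible extents.
An animal fully hidden behind an occluder yields no box — the
false-negative-by-occlusion failure mode the pipeline is designed to fix.

The oracle detector corrupts the ground-truth boxes with configurable miss,
false-positive and jitter rates, standing in for a trained neural detector.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np
import scipy.ndimage
import skimage.draw

from .frames import Box

__all__ = ["Occluder", "SceneSpec", "FrameTruth", "default_occluders",
           "generate_scene", "oracle_detector", "pen_interior", "mask_iou"]


@dataclasses.dataclass(frozen=True)
class Occluder:
    """A static occluding polygon (vertices in (x, y) pixel coords)."""

    vertices: tuple[tuple[float, float], ...]
    intensity: int


def default_occluders(width: int, height: int) -> tuple[Occluder, ...]:
    """A feeder block and a long thin pipe, scaled to the frame."""
    w, h = float(width), float(height)
    feeder = Occluder(
        vertices=(
            (0.15 * w, 0.20 * h), (0.45 * w, 0.18 * h),
            (0.47 * w, 0.38 * h), (0.13 * w, 0.36 * h),
        ),
        intensity=45,
    )
    pipe = Occluder(
        vertices=(
            (0.55 * w, 0.58 * h), (0.95 * w, 0.55 * h),
            (0.95 * w, 0.63 * h), (0.55 * w, 0.66 * h),
        ),
        intensity=60,
    )
    return (feeder, pipe)


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic pen scene; the seed fixes everything."""

    width: int = 256
    height: int = 144
    n_frames: int = 300
    floor_intensity: int = 80
    floor_texture: float = 5.0
    occluders: tuple[Occluder, ...] | None = None  # None -> default_occluders
    n_animals: int = 5
    semi_major_range: tuple[float, float] = (26.0, 34.0)
    semi_minor_range: tuple[float, float] = (12.0, 15.0)
    animal_intensity_range: tuple[int, int] = (160, 220)
    speed_range: tuple[float, float] = (3.0, 5.0)
    home_range: float | None = None  # None: free roaming over the whole pen
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.n_frames < 0:
            raise ValueError("invalid scene dimensions")
        if self.n_animals < 0:
            raise ValueError("animal count must be >= 0")
        margin = 2 * self.semi_major_range[1]
        if margin >= self.width or margin >= self.height:
            raise ValueError("animals larger than the pen")


@dataclasses.dataclass
class FrameTruth:
    """One rendered frame plus everything needed to check the pipeline."""

    frame: np.ndarray                 # uint8 (H, W), rendered with noise
    background: np.ndarray            # uint8 (H, W), animal-free scene
    occluder_mask: np.ndarray         # bool (H, W)
    full_masks: list[np.ndarray]      # per-animal bool masks, unoccluded
    visible_masks: list[np.ndarray]   # full minus occluders
    boxes: list[Box]                  # tight boxes of the visible masks


def _render_static(spec: SceneSpec, rng: np.random.Generator):
    """Floor texture, occluder raster and the composed true background."""
    floor = spec.floor_intensity + spec.floor_texture * scipy.ndimage.gaussian_filter(
        rng.standard_normal((spec.height, spec.width)), sigma=4.0
    ) / 0.06  # gaussian_filter shrinks the std; rescale to ~unit before amplitude
    floor = np.clip(np.floor(floor + 0.5), 0, 255).astype(np.uint8)
    occluders = spec.occluders
    if occluders is None:
        occluders = default_occluders(spec.width, spec.height)
    occ_mask = np.zeros((spec.height, spec.width), dtype=bool)
    occ_image = floor.copy()
    for occ in occluders:
        xs = np.array([v[0] for v in occ.vertices])
        ys = np.array([v[1] for v in occ.vertices])
        rr, cc = skimage.draw.polygon(ys, xs, shape=occ_mask.shape)
        occ_mask[rr, cc] = True
        occ_image[rr, cc] = occ.intensity
    return floor, occ_mask, occ_image


@dataclasses.dataclass
class _Animal:
    cx: float
    cy: float
    heading: float
    speed: float
    a: float  # semi-major (along heading)
    b: float  # semi-minor
    intensity: int
    home_x: float = 0.0
    home_y: float = 0.0


def _spawn_animals(spec: SceneSpec, rng: np.random.Generator) -> list[_Animal]:
    animals = []
    for _ in range(spec.n_animals):
        a = rng.uniform(*spec.semi_major_range)
        b = rng.uniform(*spec.semi_minor_range)
        cx = rng.uniform(a, spec.width - 1 - a)
        cy = rng.uniform(a, spec.height - 1 - a)
        animals.append(_Animal(
            cx=cx,
            cy=cy,
            heading=rng.uniform(0, 2 * np.pi),
            speed=rng.uniform(*spec.speed_range),
            a=a,
            b=b,
            intensity=int(rng.integers(spec.animal_intensity_range[0],
                                       spec.animal_intensity_range[1] + 1)),
            home_x=cx,
            home_y=cy,
        ))
    return animals


def _step_animal(an: _Animal, spec: SceneSpec, rng: np.random.Generator) -> None:
    """Patrol step: persistent heading with jitter, billiard wall reflection.

    With a finite ``home_range`` the heading is additionally biased back
    toward the animal's anchor once it strays too far, emulating the local
    milling of a very densely stocked pen; by default animals roam freely.
    """
    if spec.home_range is not None:
        dx, dy = an.home_x - an.cx, an.home_y - an.cy
        if np.hypot(dx, dy) > spec.home_range:
            target = np.arctan2(dy, dx)
            delta = np.angle(np.exp(1j * (target - an.heading)))
            an.heading += 0.3 * delta
    an.heading += rng.normal(0.0, 0.25)
    nx = an.cx + an.speed * np.cos(an.heading)
    ny = an.cy + an.speed * np.sin(an.heading)
    if nx < an.a or nx > spec.width - 1 - an.a:
        an.heading = np.pi - an.heading
        nx = np.clip(nx, an.a, spec.width - 1 - an.a)
    if ny < an.a or ny > spec.height - 1 - an.a:
        an.heading = -an.heading
        ny = np.clip(ny, an.a, spec.height - 1 - an.a)
    an.cx, an.cy = float(nx), float(ny)


def _animal_mask(an: _Animal, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = skimage.draw.ellipse(
        an.cy, an.cx, an.b, an.a, shape=shape, rotation=-an.heading
    )
    mask[rr, cc] = True
    return mask


def _visible_box(visible: np.ndarray) -> Box | None:
    ys, xs = np.nonzero(visible)
    if ys.size == 0:
        return None
    return Box(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def generate_scene(spec: SceneSpec) -> Iterator[FrameTruth]:
    """Yield the scene frame by frame; identical spec ⇒ identical sequence."""
    rng = np.random.default_rng(spec.seed)
    floor, occ_mask, background = _render_static(spec, rng)
    animals = _spawn_animals(spec, rng)
    for _ in range(spec.n_frames):
        canvas = floor.astype(np.float64).copy()
        full_masks, visible_masks, boxes = [], [], []
        for an in animals:
            mask = _animal_mask(an, canvas.shape)
            canvas[mask] = an.intensity
            full_masks.append(mask)
        # occluders render on top of the animals
        canvas[occ_mask] = background[occ_mask]
        for mask in full_masks:
            visible = mask & ~occ_mask
            visible_masks.append(visible)
            box = _visible_box(visible)
            if box is not None:
                boxes.append(box)
        if spec.noise_sigma > 0:
            canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
        frame = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
        yield FrameTruth(
            frame=frame,
            background=background,
            occluder_mask=occ_mask,
            full_masks=full_masks,
            visible_masks=visible_masks,
            boxes=boxes,
        )
        for an in animals:
            _step_animal(an, spec, rng)


def oracle_detector(
    truth: FrameTruth,
    miss_rate: float = 0.0,
    fp_rate: float = 0.0,
    jitter: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[Box]:
    """Ground-truth boxes corrupted like an imperfect neural detector.

    Each true box is dropped independently with probability ``miss_rate``;
    surviving corners are perturbed by uniform noise in ``[-jitter, jitter]``;
    spurious boxes arrive at Poisson rate ``fp_rate`` per frame.  Confidences
    are drawn uniformly in (0, 1].
    """
    if not (0.0 <= miss_rate <= 1.0 and 0.0 <= fp_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    h, w = truth.frame.shape[:2]
    out: list[Box] = []
    for b in truth.boxes:
        if rng.random() < miss_rate:
            continue
        d = rng.uniform(-jitter, jitter, size=4) if jitter > 0 else np.zeros(4)
        x0, y0 = b.x_min + d[0], b.y_min + d[1]
        x1, y1 = b.x_max + d[2], b.y_max + d[3]
        if x1 - x0 < 1:
            x1 = x0 + 1
        if y1 - y0 < 1:
            y1 = y0 + 1
        conf = 1.0 - rng.random()  # uniform in (0, 1]
        out.append(Box(x0, y0, x1, y1, conf).clip(w, h))
    for _ in range(rng.poisson(fp_rate)):
        bw = rng.uniform(8, w / 3)
        bh = rng.uniform(8, h / 3)
        x0 = rng.uniform(0, w - bw)
        y0 = rng.uniform(0, h - bh)
        out.append(Box(x0, y0, x0 + bw, y0 + bh, 1.0 - rng.random()))
    return out


def pen_interior(spec: SceneSpec) -> np.ndarray:
    """Boolean mask of the pen interior: the frame eroded by one body length.

    Animal centers reflect off the walls at a margin of one semi-major axis,
    so the outermost band of the frame is only ever grazed tangentially and
    carries almost no occupancy evidence — like the wall footprint of a real
    pen.  Occupancy-based estimates (the facility map in particular) are
    meaningful inside this region.
    """
    margin = int(np.ceil(spec.semi_major_range[1]))
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    mask[margin:spec.height - margin, margin:spec.width - margin] = True
    return mask


def mask_iou(a: np.ndarray, b: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Intersection over union of two binary masks, optionally within a ROI."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if roi is not None:
        roi = np.asarray(roi) > 0
        a, b = a & roi, b & roi
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
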