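"""Composite detector-input images built from the pipeline's state images.

Four 1-channel variants are derived per frame and stacked in triples as a
3-channel detector input:

* **A** — CLAHE-enhanced gray frame with facility pixels forced to 255
  (occluders whitened so the detector ignores them); bottom pad 255.
* **B** — difference image with facility pixels forced to 0 (background and
  occluders suppressed, animals emphasized); bottom pad 0.
* **C** — original gray values on foreground pixels, 0 elsewhere (the
  isolated animals); bottom pad 0.
* **D** — the complement: 0 on foreground pixels, original values elsewhere
  (animal silhouettes cut out of the floor texture); bottom pad 0.

Every variant is padded at the bottom by 32 rows, emulating the occluding
wall that borders the bottom of the camera view.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["CHANNEL_VARIANTS", "apply_clahe", "pad_bottom", "make_channel",
           "compose_three", "default_triple"]

CHANNEL_VARIANTS = ("A", "B", "C", "D")

DEFAULT_CLIP_LIMIT = 0.6
DEFAULT_TILE_GRID = (2, 2)
DEFAULT_PAD = 32


def _clipped_lut(hist: np.ndarray, clip: int, tile_area: int) -> np.ndarray:
    """Clip a tile histogram, redistribute the excess, return the 0-255 LUT."""
    excess = int(np.maximum(hist - clip, 0).sum())
    hist = np.minimum(hist, clip)
    if excess > 0:
        batch, residual = divmod(excess, 256)
        hist = hist + batch
        hist[:residual] += 1  # remainder spread over the lowest bins
    cdf = np.cumsum(hist)
    return np.clip(np.floor(cdf * (255.0 / tile_area) + 0.5), 0, 255).astype(np.uint8)


def apply_clahe(
    image: np.ndarray,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tile_grid: tuple[int, int] = DEFAULT_TILE_GRID,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is split into a ``tile_grid`` of blocks; each block's histogram
    is clipped at ``clip_limit * tile_area / 256`` counts (at least 1, the
    relative-multiplier convention) with the excess redistributed uniformly,
    and the per-tile equalization LUTs are blended bilinearly between tile
    centers.  Images whose dimensions do not divide the grid are
    reflect-padded before processing and cropped after.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    gh, gw = int(tile_grid[0]), int(tile_grid[1])
    if gh <= 0 or gw <= 0:
        raise ValueError("tile grid must be positive")
    image = np.asarray(image, dtype=np.uint8)
    if image.ndim != 2:
        raise ValueError("CLAHE operates on gray images")
    h0, w0 = image.shape
    pad_h = (-h0) % gh
    pad_w = (-w0) % gw
    work = np.pad(image, ((0, pad_h), (0, pad_w)), mode="reflect") if pad_h or pad_w else image
    h, w = work.shape
    th, tw = h // gh, w // gw
    tile_area = th * tw
    clip = max(1, int(clip_limit * tile_area / 256.0))

    luts = np.empty((gh, gw, 256), dtype=np.uint8)
    for ty in range(gh):
        for tx in range(gw):
            tile = work[ty * th:(ty + 1) * th, tx * tw:(tx + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256)
            luts[ty, tx] = _clipped_lut(hist, clip, tile_area)

    # bilinear blend between the LUTs of the four surrounding tile centers
    ys = np.arange(h, dtype=np.float64)
    xs = np.arange(w, dtype=np.float64)
    fy = np.clip((ys - (th - 1) / 2.0) / th, 0.0, gh - 1.0)
    fx = np.clip((xs - (tw - 1) / 2.0) / tw, 0.0, gw - 1.0)
    y0 = np.minimum(fy.astype(int), gh - 1)
    x0 = np.minimum(fx.astype(int), gw - 1)
    y1 = np.minimum(y0 + 1, gh - 1)
    x1 = np.minimum(x0 + 1, gw - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]
    y0g, x0g = y0[:, None], x0[None, :]
    y1g, x1g = y1[:, None], x1[None, :]
    v00 = luts[y0g, x0g, work].astype(np.float64)
    v01 = luts[y0g, x1g, work].astype(np.float64)
    v10 = luts[y1g, x0g, work].astype(np.float64)
    v11 = luts[y1g, x1g, work].astype(np.float64)
    out = ((1 - wy) * ((1 - wx) * v00 + wx * v01) + wy * ((1 - wx) * v10 + wx * v11))
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return out[:h0, :w0]


def pad_bottom(image: np.ndarray, pad: int = DEFAULT_PAD, fill: int = 0) -> np.ndarray:
    """Append ``pad`` rows of constant ``fill`` intensity at the bottom."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    image = np.asarray(image, dtype=np.uint8)
    if pad == 0:
        return image.copy()
    rows = np.full((pad,) + image.shape[1:], fill, dtype=np.uint8)
    return np.concatenate([image, rows], axis=0)


def make_channel(
    variant: str,
    input_gray: np.ndarray,
    clahe_gray: np.ndarray,
    diff: np.ndarray,
    foreground: np.ndarray,
    facility: np.ndarray,
    pad: int = DEFAULT_PAD,
) -> np.ndarray:
    """Build one 1-channel composite variant (see module docstring)."""
    shapes = {a.shape for a in (input_gray, clahe_gray, diff, foreground, facility)}
    if len(shapes) != 1:
        raise ValueError(f"input dimension mismatch: {shapes}")
    fac = facility > 0
    fg = foreground > 0
    if variant == "A":
        out = clahe_gray.copy()
        out[fac] = 255
        return pad_bottom(out, pad, fill=255)
    if variant == "B":
        out = diff.copy()
        out[fac] = 0
        return pad_bottom(out, pad, fill=0)
    if variant == "C":
        out = np.where(fg, input_gray, 0).astype(np.uint8)
        return pad_bottom(out, pad, fill=0)
    if variant == "D":
        out = np.where(fg, 0, input_gray).astype(np.uint8)
        return pad_bottom(out, pad, fill=0)
    raise ValueError(f"unknown channel variant: {variant!r}")


def default_triple(preset: str) -> tuple[str, str, str]:
    """Preset 'composite-X': the three variants other than X, alphabetical."""
    name = preset.upper().removeprefix("COMPOSITE-")
    if name not in CHANNEL_VARIANTS:
        raise ValueError(f"unknown composite preset: {preset!r}")
    return tuple(v for v in CHANNEL_VARIANTS if v != name)  # type: ignore[return-value]


def compose_three(
    triple: Sequence[str], channels: dict[str, np.ndarray], allow_repeats: bool = False
) -> np.ndarray:
    """Stack three named channel images into an (H, W, 3) composite."""
    if len(triple) != 3:
        raise ValueError("a composite needs exactly three channels")
    if not allow_repeats and len(set(triple)) != 3:
        raise ValueError(f"repeated variant in triple {tuple(triple)}")
    planes = []
    for name in triple:
        if name not in channels:
            raise ValueError(f"channel {name!r} not provided")
        planes.append(np.asarray(channels[name], dtype=np.uint8))
    if len({p.shape for p in planes}) != 1:
        raise ValueError("channel dimension mismatch")
    return np.stack(planes, axis=-1)
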