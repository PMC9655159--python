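"""The per-frame processing loop tying all stages together.

Per frame, sequentially: fetch -> grayscale -> resize/warp -> detector ->
NMS -> background update -> difference image -> facility update (with
automatic calibration) -> threshold update -> foreground mask -> composite
channels.  States are checkpointed at a configurable cadence, and a manifest
records every artifact written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from . import background as bg
from . import composite as comp
from . import facility as fac
from . import npps
from .config import PipelineConfig
from .frames import Box, nms, read_boxes, resize_frame, to_grayscale, write_boxes, write_frame
from .perspective import WarpQuad, WarpSpec, build_warp, warp_frame

__all__ = ["Detector", "FileBoxDetector", "PipelineState", "run_pipeline"]

logger = logging.getLogger(__name__)

# A detector maps a gray frame to detection boxes (within the frame).
Detector = Callable[[np.ndarray, int], Sequence[Box]]


class FileBoxDetector:
    """Detector that replays pre-computed YOLO box files, one per frame."""

    def __init__(self, boxes_dir: str | Path):
        self.paths = sorted(Path(boxes_dir).glob("*.txt"))
        if not self.paths:
            raise ValueError(f"no box files in {boxes_dir}")

    def __call__(self, frame: np.ndarray, frame_index: int) -> list[Box]:
        if frame_index >= len(self.paths):
            return []
        h, w = frame.shape[:2]
        return read_boxes(self.paths[frame_index], w, h)


@dataclasses.dataclass
class PipelineState:
    """All streaming state after a run, for inspection or continuation."""

    background: bg.BackgroundState
    facility: fac.FacilityState
    thresholds: npps.ThresholdMap
    warp_spec: WarpSpec | None
    frames_processed: int
    manifest: dict


def _detect(detector: Detector, frame: np.ndarray, index: int,
            cfg: PipelineConfig, retries: int = 2) -> list[Box]:
    h, w = frame.shape[:2]
    for attempt in range(retries + 1):
        try:
            boxes = [b.clip(w, h) for b in detector(frame, index)
                     if b.confidence >= cfg.detector.conf_threshold]
            return nms(boxes, cfg.detector.nms_iou)
        except Exception:  # noqa: BLE001 - detector plugins are untrusted
            if attempt == retries:
                logger.exception("detector failed on frame %d; skipping boxes", index)
                return []
    return []


def run_pipeline(
    frames: Iterable[np.ndarray],
    detector: Detector,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineState:
    """Run the full streaming pipeline over a frame sequence.

    ``frames`` may be gray or color; color frames are converted.  With an
    ``out_dir``, per-frame boxes, foreground masks and composites plus
    periodic state checkpoints are written and listed in ``manifest.json``.
    Input frames are never modified on disk.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    manifest: dict = {"frames": 0, "outputs": [], "checkpoints": []}

    warp_spec: WarpSpec | None = None
    bg_state = fac_state = tmap = None
    n = 0

    def _save(kind: str, name: str, image: np.ndarray) -> None:
        if out is None:
            return
        path = out / kind / name
        write_frame(image, path)
        manifest["outputs"].append(str(path.relative_to(out)))

    for index, frame in enumerate(frames):
        gray = to_grayscale(np.asarray(frame))
        dst_w, dst_h = cfg.warp.out_size
        if cfg.warp.enabled:
            if warp_spec is None:
                q = cfg.warp.quad
                quad = WarpQuad((q[0], q[1]), (q[2], q[3]), (q[4], q[5]), (q[6], q[7]))
                warp_spec = build_warp(quad, gray.shape[1], gray.shape[0], dst_w, dst_h)
            gray = warp_frame(gray, warp_spec)
        elif gray.shape != (dst_h, dst_w):
            gray = resize_frame(gray, dst_w, dst_h)

        boxes = _detect(detector, gray, index, cfg)

        if bg_state is None:
            bg_state = bg.init_background(
                gray, compare=cfg.background.compare, box_mode=cfg.background.box_mode
            )
            fac_state = fac.init_facility(
                gray.shape[1], gray.shape[0],
                calibration_interval=cfg.facility.interval,
                noise_ceiling=cfg.facility.noise_ceiling,
                cutoff=cfg.facility.cutoff,
            )
            diff = bg.difference_image(gray, bg_state)
            tmap = npps.init_thresholds(
                diff, min_thresh=cfg.npps.min_thresh, max_thresh=cfg.npps.max_thresh
            )
        else:
            bg.update_background(bg_state, gray, boxes)
            diff = bg.difference_image(gray, bg_state)
            fac.update_facility(fac_state, diff, boxes)
            npps.update_thresholds(tmap, diff, boxes)

        fg = npps.foreground_mask(diff, tmap)
        fmask = np.where(fac_state.facility >= fac_state.cutoff, 255, 0).astype(np.uint8)

        if out is not None:
            stem = f"{index:06d}"
            write_boxes(boxes, out / "boxes" / f"{stem}.txt",
                        gray.shape[1], gray.shape[0])
            manifest["outputs"].append(f"boxes/{stem}.txt")
            if cfg.save_masks:
                _save("foreground", f"{stem}.png", fg)
            if cfg.save_composites:
                clahe = comp.apply_clahe(gray, cfg.composite.clahe_clip,
                                         cfg.composite.clahe_grid)
                channels = {
                    v: comp.make_channel(v, gray, clahe, diff, fg, fmask,
                                         pad=cfg.composite.pad)
                    for v in comp.CHANNEL_VARIANTS
                }
                _save("composite", f"{stem}.png",
                      comp.compose_three(cfg.composite.triple, channels,
                                         cfg.composite.allow_repeats))

        n = index + 1
        if n % cfg.checkpoint_every == 0:
            _save("background", f"{n:06d}.png", bg_state.background)
            _save("facility", f"{n:06d}.png", fac_state.facility)
            _save("thresholds", f"{n:06d}.png",
                  np.clip(tmap.thresholds, 0, 255).astype(np.uint8))
            stats = {
                "frame": n,
                "mean_abs_diff": float(diff.mean()),
                "facility_saturated": int((fac_state.facility == 255).sum()),
                "mean_threshold": float(tmap.thresholds.mean()),
            }
            manifest["checkpoints"].append(stats)
            logger.info("checkpoint %s", stats)

    if n == 0:
        raise ValueError("empty frame source")

    manifest["frames"] = n
    if out is not None:
        _save("background", "final.png", bg_state.background)
        _save("facility", "final.png", fac_state.facility)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineState(
        background=bg_state, facility=fac_state, thresholds=tmap,
        warp_spec=warp_spec, frames_processed=n, manifest=manifest,
    )
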