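"""Pipeline configuration: dataclasses, YAML loading, strict validation.

Defaults follow the deployed system's operating constants: a 512x288
working resolution, a 10,000-frame facility calibration interval with a
noise ceiling of 245, CLAHE at clip limit 0.6 on a (2, 2) tile grid, a
32-pixel bottom pad, and NPPS threshold bounds of [10, 245].
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

__all__ = ["WarpConfig", "BackgroundConfig", "FacilityConfig", "NppsConfig",
           "CompositeConfig", "DetectorConfig", "PipelineConfig", "load_config"]


def _from_dict(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclasses.dataclass(frozen=True)
class WarpConfig:
    enabled: bool = False
    quad: tuple[float, ...] | None = None  # 8 numbers: TL, TR, BR, BL as x,y pairs
    out_size: tuple[int, int] = (512, 288)  # width, height

    def __post_init__(self) -> None:
        if self.quad is not None:
            object.__setattr__(self, "quad", tuple(float(v) for v in self.quad))
            if len(self.quad) != 8:
                raise ValueError("warp.quad needs exactly 8 numbers (4 x,y pairs)")
        object.__setattr__(self, "out_size", tuple(int(v) for v in self.out_size))
        if len(self.out_size) != 2 or min(self.out_size) <= 0:
            raise ValueError("warp.out_size must be two positive integers")
        if self.enabled and self.quad is None:
            raise ValueError("warp.enabled requires warp.quad")


@dataclasses.dataclass(frozen=True)
class BackgroundConfig:
    compare: str = "background"   # or 'prev_frame'
    box_mode: str = "hold"        # or 'frame_mean'

    def __post_init__(self) -> None:
        if self.compare not in ("background", "prev_frame"):
            raise ValueError(f"background.compare: {self.compare!r}")
        if self.box_mode not in ("hold", "frame_mean"):
            raise ValueError(f"background.box_mode: {self.box_mode!r}")


@dataclasses.dataclass(frozen=True)
class FacilityConfig:
    interval: int = 10_000
    noise_ceiling: int = 245
    cutoff: int = 255

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("facility.interval must be positive")
        if not 0 <= self.noise_ceiling <= 255 or not 0 <= self.cutoff <= 255:
            raise ValueError("facility intensities must be in [0, 255]")


@dataclasses.dataclass(frozen=True)
class NppsConfig:
    min_thresh: int = 10
    max_thresh: int = 245

    def __post_init__(self) -> None:
        if not 0 <= self.min_thresh <= self.max_thresh <= 255:
            raise ValueError("npps thresholds must satisfy 0 <= min <= max <= 255")


@dataclasses.dataclass(frozen=True)
class CompositeConfig:
    triple: tuple[str, str, str] = ("A", "B", "C")
    pad: int = 32
    clahe_clip: float = 0.6
    clahe_grid: tuple[int, int] = (2, 2)
    allow_repeats: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "triple", tuple(str(v).upper() for v in self.triple))
        object.__setattr__(self, "clahe_grid", tuple(int(v) for v in self.clahe_grid))
        if len(self.triple) != 3 or any(v not in "ABCD" for v in self.triple):
            raise ValueError("composite.triple must name three of A, B, C, D")
        if self.pad < 0:
            raise ValueError("composite.pad must be >= 0")
        if self.clahe_clip <= 0 or min(self.clahe_grid) <= 0:
            raise ValueError("composite CLAHE parameters must be positive")


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    name: str = "boxes_dir"   # 'boxes_dir' or 'oracle'
    params: dict = dataclasses.field(default_factory=dict)
    nms_iou: float = 0.5
    conf_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nms_iou <= 1.0:
            raise ValueError("detector.nms_iou must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    warp: WarpConfig = WarpConfig()
    background: BackgroundConfig = BackgroundConfig()
    facility: FacilityConfig = FacilityConfig()
    npps: NppsConfig = NppsConfig()
    composite: CompositeConfig = CompositeConfig()
    detector: DetectorConfig = DetectorConfig()
    checkpoint_every: int = 20_000
    save_composites: bool = True
    save_masks: bool = True

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        nested = {
            "warp": WarpConfig, "background": BackgroundConfig,
            "facility": FacilityConfig, "npps": NppsConfig,
            "composite": CompositeConfig, "detector": DetectorConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, sub_cls in nested.items():
            if key in data:
                kwargs[key] = _from_dict(sub_cls, data.pop(key) or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data or {})
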