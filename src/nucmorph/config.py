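"""Flat key=value run configuration, shared by the CLI commands."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields

from .autocrop import AutocropConfig
from .domains import DomainParams
from .segmentation import SegmentationConfig
from .stack import Calibration


@dataclass
class RunConfig:
    """All tunables of a run; round-trips through a key=value text file."""

    x_cal_um: float = 1.0
    y_cal_um: float = 1.0
    z_cal_um: float = 1.0
    padding_voxels: int = 20
    min_volume_um3: float = 1.0
    merge_boxes: bool = True
    merge_fraction: float = 0.5
    threshold_window: int = 20
    seg_min_volume_um3: float = 0.5
    seg_max_volume_um3: float = 2000.0
    surfel_smoothing_iterations: int = 2
    cc_contrast_factor: float = 1.5
    fish_contrast_factor: float = 2.0
    domain_min_volume_um3: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.x_cal_um, self.y_cal_um, self.z_cal_um) <= 0:
            raise ValueError("calibration must be strictly positive")
        if self.padding_voxels < 0 or not (0 < self.merge_fraction <= 1):
            raise ValueError("autocrop parameters out of range")
        if self.threshold_window < 0 or self.surfel_smoothing_iterations < 0:
            raise ValueError("segmentation parameters out of range")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.x_cal_um, self.y_cal_um, self.z_cal_um)

    def autocrop(self) -> AutocropConfig:
        return AutocropConfig(
            padding_voxels=self.padding_voxels,
            min_volume_um3=self.min_volume_um3,
            merge_boxes=self.merge_boxes,
            merge_fraction=self.merge_fraction,
        )

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            threshold_window=self.threshold_window,
            min_volume_um3=self.seg_min_volume_um3,
            max_volume_um3=self.seg_max_volume_um3,
        )

    def domain_params(self, channel: str) -> DomainParams:
        factor = self.cc_contrast_factor if channel == "chromocenter" else self.fish_contrast_factor
        return DomainParams(
            contrast_factor=factor,
            min_volume_um3=self.domain_min_volume_um3,
            channel=channel,
        )

    def to_file(self, path: str | os.PathLike) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}={str(v).lower() if isinstance(v, bool) else v}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "bool": lambda s: s.lower() in ("1", "true", "yes")}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {raw!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"unknown config key: {key}")
                values[key] = casts[types[key]](val)
        return cls(**values)
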