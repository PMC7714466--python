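"""Calibrated image stacks, bounding boxes and coordinate tables.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` (scikit-image order);
* physical calibration is carried as per-axis voxel sizes in micrometres,
  named ``(x, y, z)`` the way acquisition software reports them;
* bounding boxes are 0-based with *exclusive* extents (``width`` voxels
  starting at ``x_start``), which round-trips losslessly through the
  tab-separated coordinate table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import tifffile


class Calibration(NamedTuple):
    """Physical voxel size in µm along x, y and z."""

    x: float = 1.0
    y: float = 1.0
    z: float = 1.0

    @property
    def voxel_volume(self) -> float:
        return self.x * self.y * self.z

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        """Spacing in array-axis order, e.g. for distance transforms."""
        return (self.z, self.y, self.x)

    def validate(self) -> "Calibration":
        if not all(v > 0 for v in self):
            raise ValueError(f"calibration must be strictly positive, got {self}")
        return self


@dataclass
class CalibratedStack:
    """A single-channel 3D intensity grid with physical voxel sizes."""

    data: np.ndarray
    calibration: Calibration = Calibration()
    name: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # 2D images are handled as single-slice stacks
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {self.data.shape}")
        self.calibration = Calibration(*self.calibration).validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def crop(self, box: "BoundingBox3D") -> "CalibratedStack":
        sub = self.data[box.slices]
        return replace(self, data=sub.copy(), name=f"{self.name}_{box.id}" if self.name else str(box.id))


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned voxel box: origin + extents, clamped inside its stack."""

    id: int
    x_start: int
    y_start: int
    z_start: int
    width: int
    height: int
    depth: int

    def __post_init__(self) -> None:
        if min(self.x_start, self.y_start, self.z_start) < 0:
            raise ValueError(f"box origin must be non-negative: {self}")
        if min(self.width, self.height, self.depth) < 1:
            raise ValueError(f"box extents must be >= 1: {self}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.z_start, self.z_start + self.depth),
            slice(self.y_start, self.y_start + self.height),
            slice(self.x_start, self.x_start + self.width),
        )

    @property
    def volume_voxels(self) -> int:
        return self.width * self.height * self.depth

    def intersection_voxels(self, other: "BoundingBox3D") -> int:
        dx = min(self.x_start + self.width, other.x_start + other.width) - max(self.x_start, other.x_start)
        dy = min(self.y_start + self.height, other.y_start + other.height) - max(self.y_start, other.y_start)
        dz = min(self.z_start + self.depth, other.z_start + other.depth) - max(self.z_start, other.z_start)
        if dx <= 0 or dy <= 0 or dz <= 0:
            return 0
        return dx * dy * dz

    def union(self, other: "BoundingBox3D", new_id: int = 0) -> "BoundingBox3D":
        x0 = min(self.x_start, other.x_start)
        y0 = min(self.y_start, other.y_start)
        z0 = min(self.z_start, other.z_start)
        return BoundingBox3D(
            id=new_id,
            x_start=x0,
            y_start=y0,
            z_start=z0,
            width=max(self.x_start + self.width, other.x_start + other.width) - x0,
            height=max(self.y_start + self.height, other.y_start + other.height) - y0,
            depth=max(self.z_start + self.depth, other.z_start + other.depth) - z0,
        )

    def contains_mask(self, mask: np.ndarray) -> bool:
        """True if every foreground voxel of ``mask`` lies inside this box."""
        zz, yy, xx = np.nonzero(mask)
        if zz.size == 0:
            return True
        return (
            zz.min() >= self.z_start
            and zz.max() < self.z_start + self.depth
            and yy.min() >= self.y_start
            and yy.max() < self.y_start + self.height
            and xx.min() >= self.x_start
            and xx.max() < self.x_start + self.width
        )


_TABLE_COLUMNS = ["FileName", "id", "XStart", "YStart", "ZStart", "width", "height", "depth"]


@dataclass
class CoordinateTable:
    """The autocrop coordinate table: one row per padded bounding box."""

    source: str = ""
    boxes: list[BoundingBox3D] = field(default_factory=list)

    def renumbered(self) -> "CoordinateTable":
        boxes = [replace(b, id=i) for i, b in enumerate(self.boxes)]
        return CoordinateTable(source=self.source, boxes=boxes)

    def to_tsv(self, path: str | os.PathLike) -> None:
        lines = ["\t".join(_TABLE_COLUMNS)]
        for b in self.boxes:
            lines.append(
                "\t".join(
                    str(v)
                    for v in (self.source, b.id, b.x_start, b.y_start, b.z_start, b.width, b.height, b.depth)
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CoordinateTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _TABLE_COLUMNS:
                raise ValueError(f"unrecognized coordinate table header: {header}")
            source = ""
            boxes = []
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                source = parts[0]
                vals = [int(v) for v in parts[1:8]]
                boxes.append(BoundingBox3D(*vals))
        return cls(source=source, boxes=boxes)


@dataclass
class NucleusMask:
    """A segmented nucleus: binary grid + calibration + provenance."""

    mask: np.ndarray
    calibration: Calibration = Calibration()
    method: str = "otsu"  # otsu | gift | bad_crop
    crop_id: int | str = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("nucleus mask must be 3D")
        self.calibration = Calibration(*self.calibration).validate()

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * self.calibration.voxel_volume

    @property
    def is_bad(self) -> bool:
        return self.method == "bad_crop"


def read_stack(path: str | os.PathLike, calibration: Calibration | None = None) -> CalibratedStack:
    """Read a multi-page TIFF as a stack; calibration falls back to metadata.

    ImageJ-dialect TIFFs carry XY resolution and Z spacing; when neither the
    file nor the caller provides one, unit calibration is used.
    """
    with tifffile.TiffFile(os.fspath(path)) as tif:
        data = tif.asarray()
        if calibration is None:
            calibration = _calibration_from_tiff(tif)
    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return CalibratedStack(data=data, calibration=calibration or Calibration(), name=name)


def _calibration_from_tiff(tif: tifffile.TiffFile) -> Calibration | None:
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        zs = None
        if tif.imagej_metadata:
            zs = tif.imagej_metadata.get("spacing")
        if xres and yres:
            xn, xd = xres.value
            yn, yd = yres.value
            cx = xd / xn if xn else None
            cy = yd / yn if yn else None
            if cx and cy:
                return Calibration(x=cx, y=cy, z=float(zs) if zs else 1.0)
    except Exception:
        pass
    return None


def write_stack(path: str | os.PathLike, stack: CalibratedStack | np.ndarray,
                calibration: Calibration | None = None) -> None:
    """Write a stack as an ImageJ-dialect multi-page TIFF with calibration."""
    if isinstance(stack, CalibratedStack):
        data, cal = stack.data, stack.calibration
    else:
        data, cal = np.asarray(stack), calibration or Calibration()
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(
        os.fspath(path),
        data,
        imagej=True,
        resolution=(1.0 / cal.x, 1.0 / cal.y),
        metadata={"spacing": cal.z, "unit": "um", "axes": "ZYX"},
    )


def as_uint8_bins(data: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Rescale intensities onto 0..n_bins-1 integer bins (constant-safe)."""
    data = np.asarray(data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros(data.shape, dtype=np.int32)
    scaled = (data - lo) / (hi - lo) * (n_bins - 1)
    return np.rint(scaled).astype(np.int32)
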