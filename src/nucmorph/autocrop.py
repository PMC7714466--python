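"""Automatic extraction of nucleus-sized objects from wide-field stacks.

Pipeline: Otsu threshold on a 256-bin histogram of the whole stack →
26-connected components → physical-volume filter (> 1 µm³ by default,
which discards autofluorescent debris such as chloroplasts) → padded
bounding boxes (20 voxels by default) → optional merging of boxes with
large mutual overlap → per-object crops, a coordinate table and an
annotated maximum-intensity Z-projection.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .stack import (
    BoundingBox3D,
    CalibratedStack,
    Calibration,
    CoordinateTable,
    as_uint8_bins,
    write_stack,
)

log = logging.getLogger(__name__)

#: 26-connectivity structuring element for 3D blob labelling
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SingleClassError(ValueError):
    """The intensity histogram has fewer than two populated bins."""


@dataclass
class AutocropConfig:
    padding_voxels: int = 20
    min_volume_um3: float = 1.0
    merge_boxes: bool = True
    merge_fraction: float = 0.5


@dataclass
class Component:
    """One 26-connected foreground component, stored tight to its bbox."""

    label: int
    slices: tuple[slice, slice, slice]
    mask: np.ndarray  # bool, within `slices`
    voxel_count: int
    volume_um3: float


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on an intensity histogram (bin index returned).

    Maximizes between-class variance; binarization convention is
    ``value > threshold`` → foreground. Raises :class:`SingleClassError`
    when fewer than two bins are populated (constant image).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1:
        raise ValueError("histogram must be 1D")
    if np.count_nonzero(hist) < 2:
        raise SingleClassError("histogram has fewer than two populated bins")
    total = hist.sum()
    p = hist / total
    omega = np.cumsum(p)  # class-0 probability for threshold t (inclusive)
    mu = np.cumsum(p * np.arange(hist.size))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def threshold_stack(stack: CalibratedStack, n_bins: int = 256) -> np.ndarray:
    """Binarize a stack with Otsu on a 256-bin rescaled histogram.

    Intensities are rescaled onto 256 bins regardless of bit depth so
    thresholds are comparable across acquisitions.
    """
    binned = as_uint8_bins(stack.data, n_bins)
    hist = np.bincount(binned.ravel(), minlength=n_bins)
    t = otsu_threshold(hist)
    return binned > t


def find_components(binary: np.ndarray, calibration: Calibration) -> list[Component]:
    """26-connected components of a binary grid with physical volumes."""
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndi.label(binary, structure=STRUCT_26)
    out: list[Component] = []
    voxel_vol = Calibration(*calibration).voxel_volume
    for i, slc in enumerate(ndi.find_objects(labels), start=1):
        m = labels[slc] == i
        cnt = int(np.count_nonzero(m))
        out.append(Component(label=i, slices=slc, mask=m, voxel_count=cnt,
                             volume_um3=cnt * voxel_vol))
    return out


def filter_components(components: list[Component], min_volume_um3: float = 1.0) -> list[Component]:
    """Keep components with volume strictly above ``min_volume_um3``."""
    kept = [c for c in components if c.volume_um3 > min_volume_um3]
    dropped = len(components) - len(kept)
    if dropped:
        log.warning("discarded %d components below %.3g um^3", dropped, min_volume_um3)
    return kept


def component_to_box(
    component: Component,
    padding_voxels: int,
    stack_shape: tuple[int, int, int],
    box_id: int = 0,
) -> BoundingBox3D:
    """Tight voxel bounding box expanded by padding, clamped to the stack."""
    if padding_voxels < 0:
        raise ValueError("padding must be >= 0")
    zs, ys, xs = component.slices
    nz, ny, nx = stack_shape
    z0 = max(zs.start - padding_voxels, 0)
    y0 = max(ys.start - padding_voxels, 0)
    x0 = max(xs.start - padding_voxels, 0)
    z1 = min(zs.stop + padding_voxels, nz)
    y1 = min(ys.stop + padding_voxels, ny)
    x1 = min(xs.stop + padding_voxels, nx)
    return BoundingBox3D(id=box_id, x_start=x0, y_start=y0, z_start=z0,
                         width=x1 - x0, height=y1 - y0, depth=z1 - z0)


def merge_boxes(boxes: list[BoundingBox3D], overlap_fraction: float = 0.5) -> list[BoundingBox3D]:
    """Union boxes sharing >= ``overlap_fraction`` of the smaller box.

    Applied iteratively to a fixed point, then renumbered from 0. Shared
    volume is measured in voxels against the smaller box of each pair.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    current = list(boxes)
    changed = True
    while changed:
        changed = False
        out: list[BoundingBox3D] = []
        for b in current:
            merged = False
            for i, a in enumerate(out):
                inter = a.intersection_voxels(b)
                if inter >= overlap_fraction * min(a.volume_voxels, b.volume_voxels):
                    out[i] = a.union(b, new_id=a.id)
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(b)
        current = out
    return [replace(b, id=i) for i, b in enumerate(current)]


# ---------------------------------------------------------------------------
# Z-projection annotation

_DIGITS = {  # 3x5 bitmap font for numbering boxes on the projection
    "0": ["111", "101", "101", "101", "111"],
    "1": ["010", "110", "010", "010", "111"],
    "2": ["111", "001", "111", "100", "111"],
    "3": ["111", "001", "111", "001", "111"],
    "4": ["101", "101", "111", "001", "001"],
    "5": ["111", "100", "111", "001", "111"],
    "6": ["111", "100", "111", "101", "111"],
    "7": ["111", "001", "010", "010", "010"],
    "8": ["111", "101", "111", "101", "111"],
    "9": ["111", "101", "111", "001", "111"],
}


def _stamp_number(img: np.ndarray, row: int, col: int, number: int, value) -> None:
    for k, ch in enumerate(str(number)):
        glyph = _DIGITS[ch]
        for r in range(5):
            for c in range(3):
                if glyph[r][c] == "1":
                    rr, cc = row + r, col + k * 4 + c
                    if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]:
                        img[rr, cc] = value


def annotated_projection(stack: CalibratedStack, boxes: list[BoundingBox3D]) -> np.ndarray:
    """Inverted maximum-intensity Z-projection with numbered box outlines."""
    proj = stack.data.max(axis=0).astype(np.float64)
    lo, hi = proj.min(), proj.max()
    inv = np.full(proj.shape, 255.0) if hi <= lo else (hi - proj) / (hi - lo) * 255.0
    img = inv.astype(np.uint8)
    for b in boxes:
        r0, r1 = b.y_start, b.y_start + b.height - 1
        c0, c1 = b.x_start, b.x_start + b.width - 1
        img[r0, c0:c1 + 1] = 0
        img[r1, c0:c1 + 1] = 0
        img[r0:r1 + 1, c0] = 0
        img[r0:r1 + 1, c1] = 0
        _stamp_number(img, r0 + 2, c0 + 2, b.id, 0)
    return img


@dataclass
class AutocropResult:
    table: CoordinateTable
    crops: list[CalibratedStack]
    projection: np.ndarray


def autocrop_stack(
    stack: CalibratedStack,
    config: AutocropConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> AutocropResult:
    """Run the full autocrop pipeline on one wide-field stack.

    Returns the coordinate table, one crop per box and the annotated
    Z-projection; when ``out_dir`` is given the three products are written
    to ``crops/``, ``tables/`` and ``projections/`` subfolders.
    """
    cfg = config or AutocropConfig()
    try:
        binary = threshold_stack(stack)
    except SingleClassError:
        log.warning("constant stack %r: no objects detected", stack.name)
        binary = np.zeros(stack.shape, dtype=bool)
    comps = find_components(binary, stack.calibration)
    comps = filter_components(comps, cfg.min_volume_um3)
    boxes = [
        component_to_box(c, cfg.padding_voxels, stack.shape, box_id=i)
        for i, c in enumerate(comps)
    ]
    if cfg.merge_boxes and boxes:
        boxes = merge_boxes(boxes, cfg.merge_fraction)
    if not boxes:
        log.warning("stack %r produced an empty coordinate table", stack.name)
    table = CoordinateTable(source=stack.name, boxes=boxes)
    crops = [stack.crop(b) for b in boxes]
    projection = annotated_projection(stack, boxes)
    log.info("stack %r: %d crops", stack.name, len(boxes))

    if out_dir is not None:
        for sub in ("crops", "tables", "projections"):
            os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
        stem = stack.name or "stack"
        for b, crop in zip(boxes, crops):
            write_stack(os.path.join(out_dir, "crops", f"{stem}_{b.id}.tif"), crop)
        table.to_tsv(os.path.join(out_dir, "tables", f"{stem}_coords.tsv"))
        write_stack(
            os.path.join(out_dir, "projections", f"{stem}_zproj.tif"),
            projection[np.newaxis],
            stack.calibration,
        )
    return AutocropResult(table=table, crops=crops, projection=projection)


def crop_other_channels(
    table: CoordinateTable,
    stacks: dict[str, CalibratedStack],
    out_dir: str | os.PathLike | None = None,
) -> dict[str, list[CalibratedStack]]:
    """Apply one coordinate table to additional channels, box-identically."""
    shapes = {name: s.shape for name, s in stacks.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"channel stacks differ in dimensions: {shapes}")
    out: dict[str, list[CalibratedStack]] = {}
    for name, s in stacks.items():
        crops = []
        for b in table.boxes:
            crop = s.crop(b)
            crop.channel = name
            crop.name = f"{table.source}_{name}_{b.id}"
            crops.append(crop)
            if out_dir is not None:
                os.makedirs(out_dir, exist_ok=True)
                write_stack(os.path.join(out_dir, f"{crop.name}.tif"), crop)
        out[name] = crops
    return out
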