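"""Single-nucleus segmentation: modified Otsu and 3D gift-wrapping.

The modified-Otsu method scans candidate thresholds in a window around the
plain Otsu value, keeps the largest connected component at each, fills
interior holes (the unstained nucleolus), and returns the mask whose
sphericity is maximal — the documented strategy for threshold selection on
single-nucleus crops whose grey-level range varies from nucleus to nucleus.

The gift-wrapping method is an edge-based refinement of that mask: the
distance-restricted convex hull (see :mod:`nucmorph.hull`) is applied slice
by slice in the three orthogonal orientations (XY, XZ, YZ) and the three
reconstructions are united. The threshold distance ``td`` is half the
radius of the volume-equivalent sphere of the input mask, so only
concavities small relative to the nucleus (nucleolus bites, staining
artifacts) are bridged while genuine shape is preserved.

Crops in which no plausible nucleus can be segmented — empty, truncated at
the crop boundary, or with volume outside configured bounds — are tagged
``bad_crop``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .autocrop import STRUCT_26, SingleClassError, otsu_threshold
from .hull import restricted_hull_2d
from .stack import CalibratedStack, Calibration, NucleusMask, as_uint8_bins
from .surface import surface_area_naive

log = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    threshold_window: int = 20  # bins scanned on each side of the Otsu value
    min_volume_um3: float = 0.5
    max_volume_um3: float = 2000.0
    sphericity_tolerance: float = 0.02  # relative slack for threshold choice
    gift_smoothing: bool = True  # final 3D hole fill after the union


def equivalent_radius(volume_um3: float) -> float:
    """Radius (µm) of the sphere with the given volume."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def compute_td(mask: NucleusMask) -> float:
    """Threshold distance: half the equivalent-sphere radius, in µm."""
    return equivalent_radius(mask.volume_um3) / 2.0


def _largest_component(binary: np.ndarray) -> np.ndarray | None:
    labels, n = ndi.label(binary, structure=STRUCT_26)
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _fill(mask: np.ndarray) -> np.ndarray:
    """Slice-wise 2D fill in Z followed by a 3D fill."""
    out = mask.copy()
    for z in range(out.shape[0]):
        if out[z].any():
            out[z] = ndi.binary_fill_holes(out[z])
    return ndi.binary_fill_holes(out)


def _touches_opposing_faces(mask: np.ndarray) -> bool:
    for axis in range(3):
        first = np.take(mask, 0, axis=axis)
        last = np.take(mask, -1, axis=axis)
        if first.any() and last.any():
            return True
    return False


def _sphericity(volume: float, area: float) -> float:
    return 36.0 * math.pi * volume**2 / area**3 if area > 0 else 0.0


def modified_otsu_segment(
    crop: CalibratedStack,
    config: SegmentationConfig | None = None,
    crop_id: int | str = 0,
) -> NucleusMask:
    """Sphericity-maximizing threshold scan around the plain Otsu value."""
    cfg = config or SegmentationConfig()
    cal = crop.calibration
    voxel_vol = cal.voxel_volume
    binned = as_uint8_bins(crop.data)

    def bad() -> NucleusMask:
        return NucleusMask(np.zeros(crop.shape, dtype=bool), cal, "bad_crop", crop_id)

    hist = np.bincount(binned.ravel(), minlength=256)
    try:
        t0 = otsu_threshold(hist)
    except SingleClassError:
        log.warning("crop %s is constant: bad crop", crop_id)
        return bad()

    candidates: list[tuple[int, float, np.ndarray]] = []
    lo = max(t0 - cfg.threshold_window, 0)
    hi = min(t0 + cfg.threshold_window, 254)
    for t in range(lo, hi + 1):
        comp = _largest_component(binned > t)
        if comp is None:
            continue
        comp = _fill(comp)
        volume = float(np.count_nonzero(comp)) * voxel_vol
        if not (cfg.min_volume_um3 <= volume <= cfg.max_volume_um3):
            continue
        area = surface_area_naive(comp, cal)
        candidates.append((t, _sphericity(volume, area), comp))
    best_mask = None
    if candidates:
        # among thresholds whose sphericity is within tolerance of the
        # optimum, keep the one nearest the plain Otsu value: the scan only
        # overrides t0 when roundness improves materially (split or bitten
        # nuclei), which avoids drifting along the flat part of the curve
        best_score = max(s for _, s, _ in candidates)
        floor = best_score * (1.0 - cfg.sphericity_tolerance)
        t_sel, _, best_mask = min(
            (c for c in candidates if c[1] >= floor),
            key=lambda c: (abs(c[0] - t0), -c[0]),
        )
    if best_mask is None or _touches_opposing_faces(best_mask):
        log.warning("crop %s: no plausible nucleus found: bad crop", crop_id)
        return bad()
    return NucleusMask(best_mask, cal, "otsu", crop_id)


def gift_wrap_segment(
    crop: CalibratedStack,
    initial: NucleusMask,
    config: SegmentationConfig | None = None,
) -> NucleusMask:
    """Slice-wise restricted hull in XY, XZ and YZ; union of the three.

    ``initial`` is the modified-Otsu mask; its volume sets ``td``. The
    output always contains the input mask and never exceeds its 3D convex
    hull. A result truncated by the crop boundary (touching two opposing
    faces) is tagged ``bad_crop``.
    """
    cfg = config or SegmentationConfig()
    cal = initial.calibration

    def bad() -> NucleusMask:
        return NucleusMask(np.zeros(initial.mask.shape, dtype=bool), cal,
                           "bad_crop", initial.crop_id)

    if initial.is_bad or initial.voxel_count == 0:
        return bad()
    td = compute_td(initial)
    m = initial.mask
    union = m.copy()
    # XY: iterate Z slices; in-plane spacing (y, x)
    for z in range(m.shape[0]):
        if m[z].any():
            union[z] |= restricted_hull_2d(m[z], td, (cal.y, cal.x))
    # XZ: iterate Y; in-plane spacing (z, x)
    for y in range(m.shape[1]):
        sl = m[:, y, :]
        if sl.any():
            union[:, y, :] |= restricted_hull_2d(sl, td, (cal.z, cal.x))
    # YZ: iterate X; in-plane spacing (z, y)
    for x in range(m.shape[2]):
        sl = m[:, :, x]
        if sl.any():
            union[:, :, x] |= restricted_hull_2d(sl, td, (cal.z, cal.y))

    out = _largest_component(union)
    if out is None:
        return bad()
    if cfg.gift_smoothing:
        out = ndi.binary_fill_holes(out)
    volume = float(np.count_nonzero(out)) * cal.voxel_volume
    if _touches_opposing_faces(out):
        log.warning("crop %s: gift-wrapped mask truncated by the crop: bad crop",
                    initial.crop_id)
        return bad()
    if not (cfg.min_volume_um3 <= volume <= cfg.max_volume_um3):
        log.warning("crop %s: gift-wrapped volume %.3g um^3 out of bounds: bad crop",
                    initial.crop_id, volume)
        return bad()
    return NucleusMask(out, cal, "gift", initial.crop_id)


def segment_crop(
    crop: CalibratedStack,
    config: SegmentationConfig | None = None,
    crop_id: int | str = 0,
) -> tuple[NucleusMask, NucleusMask]:
    """Run both methods on one crop; returns (otsu_mask, gift_mask)."""
    otsu = modified_otsu_segment(crop, config, crop_id)
    gift = gift_wrap_segment(crop, otsu, config)
    return otsu, gift
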