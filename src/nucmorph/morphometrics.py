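"""Per-nucleus shape parameters.

Volume is the calibrated voxel sum. Flatness and elongation follow the
equivalent-ellipsoid radius-ratio convention: from the eigenvalues
``l1 >= l2 >= l3`` of the covariance of the calibrated foreground voxel
coordinates, ``elongation = sqrt(l1/l2)`` and ``flatness = sqrt(l2/l3)``;
both equal 1 for a sphere. Sphericity is ``36*pi*V^2 / S^3`` computed
against the corrected (surfel) surface area, with the naive-surface
variant also reported for comparison.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import equivalent_radius
from .stack import CalibratedStack, Calibration, NucleusMask
from .surface import surface_area_naive, surface_area_surfel


class DegenerateMaskError(ValueError):
    """Mask has too few / coplanar voxels for ellipsoid fitting."""


def volume(mask: NucleusMask | np.ndarray, calibration: Calibration | None = None) -> float:
    """Physical volume: voxel count x voxel volume (µm³)."""
    if isinstance(mask, NucleusMask):
        return mask.volume_um3
    cal = Calibration(*(calibration or Calibration())).validate()
    return float(np.count_nonzero(mask)) * cal.voxel_volume


def flatness_elongation(
    mask: NucleusMask | np.ndarray, calibration: Calibration | None = None
) -> tuple[float, float]:
    """(flatness, elongation) of the equivalent ellipsoid; both >= 1."""
    if isinstance(mask, NucleusMask):
        m, cal = mask.mask, mask.calibration
    else:
        m = np.asarray(mask, dtype=bool)
        cal = Calibration(*(calibration or Calibration())).validate()
    coords = np.argwhere(m).astype(np.float64)
    if coords.shape[0] < 4:
        raise DegenerateMaskError(f"{coords.shape[0]} voxels: need >= 4 non-coplanar")
    coords *= np.array(cal.sampling_zyx)
    cov = np.cov(coords.T)
    eig = np.linalg.eigvalsh(cov)  # ascending: l3, l2, l1
    if eig[0] <= 1e-12 * max(eig[2], 1e-30):
        raise DegenerateMaskError("coplanar or collinear voxel set")
    flatness = math.sqrt(eig[1] / eig[0])
    elongation = math.sqrt(eig[2] / eig[1])
    return flatness, elongation


def sphericity(volume_um3: float, surface_um2: float) -> float:
    if surface_um2 <= 0:
        return float("nan")
    return 36.0 * math.pi * volume_um3**2 / surface_um2**3


#: column order of the morphometrics table
METRIC_COLUMNS = [
    "Crop",
    "Method",
    "Volume",
    "SurfaceArea_initial",
    "SurfaceArea_new",
    "Sphericity",
    "Sphericity_initial",
    "Flatness",
    "Elongation",
    "EquivalentRadius",
]


@dataclass
class ShapeMetrics:
    crop_id: int | str
    method: str
    volume_um3: float = float("nan")
    surface_area_initial: float = float("nan")
    surface_area_new: float = float("nan")
    sphericity: float = float("nan")
    sphericity_initial: float = float("nan")
    flatness: float = float("nan")
    elongation: float = float("nan")
    equivalent_radius_um: float = float("nan")

    def as_row(self) -> list:
        return [
            self.crop_id,
            self.method,
            self.volume_um3,
            self.surface_area_initial,
            self.surface_area_new,
            self.sphericity,
            self.sphericity_initial,
            self.flatness,
            self.elongation,
            self.equivalent_radius_um,
        ]


def nucleus_metrics(
    mask: NucleusMask,
    raw: CalibratedStack | None = None,
    smoothing_iterations: int = 2,
) -> ShapeMetrics:
    """All shape parameters for one segmented nucleus.

    ``raw`` provides the intensity crop for gradient-based normals; the
    binary mask is used when it is absent. Bad crops yield a row with the
    tag and empty metric fields.
    """
    if mask.is_bad or mask.voxel_count == 0:
        return ShapeMetrics(crop_id=mask.crop_id, method="bad_crop")
    v = mask.volume_um3
    s_initial = surface_area_naive(mask.mask, mask.calibration)
    s_new = surface_area_surfel(
        mask.mask,
        calibration=mask.calibration,
        raw=raw,
        smoothing_iterations=smoothing_iterations,
    )
    try:
        flat, elong = flatness_elongation(mask)
    except DegenerateMaskError:
        flat = elong = float("nan")
    return ShapeMetrics(
        crop_id=mask.crop_id,
        method=mask.method,
        volume_um3=v,
        surface_area_initial=s_initial,
        surface_area_new=s_new,
        sphericity=sphericity(v, s_new),
        sphericity_initial=sphericity(v, s_initial),
        flatness=flat,
        elongation=elong,
        equivalent_radius_um=equivalent_radius(v),
    )


def compile_metrics(
    masks: Sequence[NucleusMask],
    raws: Mapping[int | str, CalibratedStack] | None = None,
    smoothing_iterations: int = 2,
) -> pd.DataFrame:
    """One row per (nucleus, method); bad crops keep their tag, fields empty."""
    rows = []
    for mask in masks:
        raw = raws.get(mask.crop_id) if raws else None
        rows.append(nucleus_metrics(mask, raw, smoothing_iterations).as_row())
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metrics(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
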