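"""Synthetic inputs: digitized spheres, nucleus fields, bead stacks.

Everything the package needs for validation is generated in silico:

* **digitized spheres** — binary balls on an isotropic unit-voxel grid, the
  reference objects for the surface-area estimators;
* **synthetic nucleus fields** — wide-field-like stacks of ellipsoidal
  "nuclei" with optional bright chromocenters, a dark nucleolus (an
  intensity well mimicking the unstained nucleolus of DNA-dye images),
  anisotropic Gaussian blur and additive noise, with voxel-exact ground
  truth;
* **bead stacks** — homogeneous spheres of known physical diameter on an
  anisotropic grid, emulating fluorescent calibration microspheres.

All randomness flows from a single explicit seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .stack import CalibratedStack, Calibration, write_stack


class FixtureError(ValueError):
    """Raised when a requested synthetic object cannot be generated."""


@dataclass
class DigitizedSphere:
    """A binary ball on an isotropic grid (unit voxels)."""

    radius_voxels: int
    grid: np.ndarray  # bool, (z, y, x)
    center: tuple[int, int, int]

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.grid))

    def as_stack(self) -> CalibratedStack:
        return CalibratedStack(
            data=self.grid.astype(np.uint8),
            calibration=Calibration(1.0, 1.0, 1.0),
            name=f"sphere_r{self.radius_voxels}",
        )


def make_digitized_sphere(
    radius_voxels: int,
    margin: int = 2,
    membership: Literal["outer", "center"] = "outer",
) -> DigitizedSphere:
    """Rasterize a ball of the given radius as a binary voxel grid.

    ``membership`` selects the rasterization rule. The default ``"outer"``
    rule includes a voxel when its center lies within ``radius + 1/2``
    (equivalently, when the rounded center distance does not exceed the
    radius), so the cube faces of the digital object straddle the nominal
    sphere. The ``"center"`` rule is the strict ball ``distance <= radius``.
    """
    if not isinstance(radius_voxels, (int, np.integer)) or radius_voxels < 1:
        raise FixtureError(f"radius must be a positive integer, got {radius_voxels!r}")
    if membership not in ("outer", "center"):
        raise FixtureError(f"unknown membership rule {membership!r}")
    r_eff = radius_voxels + 0.5 if membership == "outer" else float(radius_voxels)
    half = int(math.floor(r_eff)) + max(margin, 2)
    n = 2 * half + 1
    c = half
    zz, yy, xx = np.ogrid[:n, :n, :n]
    grid = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= r_eff**2
    return DigitizedSphere(radius_voxels=int(radius_voxels), grid=grid, center=(c, c, c))


@dataclass
class FieldParams:
    """Generation parameters for a synthetic multi-nucleus field.

    Distances are micrometres; the default calibration matches a typical
    wide-field acquisition (XY 0.103 µm, Z 0.2 µm).
    """

    shape: tuple[int, int, int] = (48, 192, 192)  # (z, y, x) voxels
    calibration: Calibration = Calibration(0.103, 0.103, 0.2)
    n_nuclei: int = 9
    radius_um: tuple[float, float] = (1.2, 1.8)  # geometric-mean semi-axis
    elongation_range: tuple[float, float] = (1.0, 1.0)
    flatness_range: tuple[float, float] = (1.0, 1.0)
    intensity_range: tuple[float, float] = (0.6, 1.0)  # nucleoplasm level
    background: float = 0.02
    n_chromocenters: int = 0
    cc_intensity_ratio: float = 3.0
    cc_radius_um: float = 0.25
    cc_radial_fraction: float = 0.5
    nucleolus: bool = False
    nucleolus_radius_fraction: float = 0.45
    nucleolus_tangent: bool = False
    nucleolus_level: float = 0.2
    fish_channels: tuple[tuple[str, int], ...] = ()  # (channel, signals per nucleus)
    fish_radius_um: float = 0.25
    fish_level: float = 0.8
    fish_background: float = 0.03
    blur_sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z)
    noise_sd: float = 0.0
    min_gap_um: float = 1.0  # minimal surface-to-surface nucleus separation
    wall_gap_um: float = 0.5  # minimal nucleus-to-stack-face clearance
    max_retries: int = 500


@dataclass
class NucleusRecord:
    """Planted ground truth for one synthetic nucleus."""

    label: int
    center_um: tuple[float, float, float]  # (x, y, z)
    semi_axes_um: tuple[float, float, float]  # (x, y, z)
    level: float
    n_chromocenters: int = 0
    elongation: float = 1.0
    flatness: float = 1.0


@dataclass
class SyntheticField:
    """A generated stack plus voxel-exact ground truth."""

    stack: CalibratedStack
    channels: dict[str, np.ndarray]
    nucleus_labels: np.ndarray  # int, 0 = background, i = nucleus i
    domain_labels: dict[str, np.ndarray]  # channel -> int label grid
    records: list[NucleusRecord]
    params: FieldParams
    seed: int
    metadata: dict = dc_field(default_factory=dict)

    def nucleus_mask(self, label: int) -> np.ndarray:
        return self.nucleus_labels == label

    def save(self, out_dir: str | os.PathLike) -> None:
        """Write channels as multi-page TIFFs + label TIFFs + TSV manifest."""
        os.makedirs(out_dir, exist_ok=True)
        cal = self.stack.calibration
        for name, data in self.channels.items():
            arr = np.clip(data, 0, None)
            arr = (arr / max(arr.max(), 1e-12) * 65535).astype(np.uint16)
            write_stack(os.path.join(out_dir, f"{self.stack.name}_{name}.tif"), arr, cal)
        write_stack(
            os.path.join(out_dir, f"{self.stack.name}_labels.tif"),
            self.nucleus_labels.astype(np.uint16),
            cal,
        )
        for name, lab in self.domain_labels.items():
            write_stack(os.path.join(out_dir, f"{self.stack.name}_{name}_domains.tif"),
                        lab.astype(np.uint16), cal)
        lines = ["label\tcx_um\tcy_um\tcz_um\tax_um\tay_um\taz_um\tlevel\tn_chromocenters\tseed"]
        for r in self.records:
            lines.append(
                "\t".join(
                    f"{v:.6g}" if isinstance(v, float) else str(v)
                    for v in (r.label, *r.center_um, *r.semi_axes_um, r.level,
                              r.n_chromocenters, self.seed)
                )
            )
        with open(os.path.join(out_dir, f"{self.stack.name}_manifest.tsv"), "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _physical_axes(shape, cal: Calibration):
    z = np.arange(shape[0]) * cal.z
    y = np.arange(shape[1]) * cal.y
    x = np.arange(shape[2]) * cal.x
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _ellipsoid_mask(shape, cal: Calibration, center_um, semi_axes_um) -> np.ndarray:
    """Rasterize an axis-aligned ellipsoid; center/axes in µm as (x, y, z)."""
    cx, cy, cz = center_um
    ax, ay, az = semi_axes_um
    z, y, x = _physical_axes(shape, cal)
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _ellipsoid_radius(semi_axes_um, direction) -> float:
    """Radius of an axis-aligned ellipsoid along a unit direction (x, y, z)."""
    ax, ay, az = semi_axes_um
    dx, dy, dz = direction
    return 1.0 / math.sqrt((dx / ax) ** 2 + (dy / ay) ** 2 + (dz / az) ** 2)


def _random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def make_synthetic_field(params: FieldParams | None = None, seed: int = 0) -> SyntheticField:
    """Generate a multi-nucleus wide-field-like stack with ground truth.

    The intensity image is the sum of per-nucleus templates (nucleoplasm
    level, brighter chromocenter blobs, an optional dark nucleolus well),
    smoothed by an anisotropic Gaussian and corrupted by additive Gaussian
    noise. Identical ``(params, seed)`` give a bit-identical stack.
    """
    p = params or FieldParams()
    if p.n_nuclei < 1:
        raise FixtureError("n_nuclei must be >= 1")
    if any(s < 0 for s in p.blur_sigma_um) or p.noise_sd < 0:
        raise FixtureError("blur sigmas and noise level must be >= 0")
    rng = np.random.default_rng(seed)
    cal = Calibration(*p.calibration).validate()
    shape = tuple(p.shape)
    extent_um = (shape[2] * cal.x, shape[1] * cal.y, shape[0] * cal.z)  # (x, y, z)

    # -- place nuclei without overlap (bounded retries) --------------------
    placed: list[NucleusRecord] = []
    for i in range(p.n_nuclei):
        ok = False
        for _ in range(p.max_retries):
            r = rng.uniform(*p.radius_um)
            e = rng.uniform(*p.elongation_range)
            f = rng.uniform(*p.flatness_range)
            # semi-axes a >= b >= c with a/b = e, b/c = f, geometric mean r
            b = r * (f / e) ** (1.0 / 3)
            a, c = b * e, b / f
            # longest axis in-plane (x or y), shortest along z — as in flattened
            # adherent nuclei; the in-plane assignment is randomized
            if rng.random() < 0.5:
                axes = (a, b, c)  # (x, y, z)
            else:
                axes = (b, a, c)
            margin = [ax + p.wall_gap_um for ax in axes]
            if any(2 * m >= ext for m, ext in zip(margin, extent_um)):
                raise FixtureError(
                    f"nucleus of semi-axes {axes} µm does not fit the stack extent {extent_um} µm"
                )
            center = tuple(rng.uniform(m, ext - m) for m, ext in zip(margin, extent_um))
            far = all(
                math.dist(center, q.center_um)
                >= max(axes) + max(q.semi_axes_um) + p.min_gap_um
                for q in placed
            )
            if far:
                level = rng.uniform(*p.intensity_range)
                placed.append(NucleusRecord(label=i + 1, center_um=center,
                                            semi_axes_um=axes, level=level,
                                            elongation=e, flatness=f))
                ok = True
                break
        if not ok:
            raise FixtureError(
                f"could not place nucleus {i} after {p.max_retries} retries "
                f"(n_nuclei={p.n_nuclei}, radius_um={p.radius_um}, "
                f"min_gap_um={p.min_gap_um}, shape={shape})"
            )

    # -- render ------------------------------------------------------------
    dna = np.full(shape, p.background, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)
    cc_labels = np.zeros(shape, dtype=np.int32)
    fish_imgs = {name: np.full(shape, p.fish_background, dtype=np.float64)
                 for name, _ in p.fish_channels}
    fish_labels = {name: np.zeros(shape, dtype=np.int32) for name, _ in p.fish_channels}
    next_cc = 1
    next_fish = {name: 1 for name, _ in p.fish_channels}

    for rec in placed:
        m = _ellipsoid_mask(shape, cal, rec.center_um, rec.semi_axes_um)
        labels[m] = rec.label
        dna[m] = rec.level

        def _blob_centers(k: int, radius_um: float) -> list[tuple[float, float, float]]:
            centers: list[tuple[float, float, float]] = []
            for _ in range(p.max_retries):
                if len(centers) == k:
                    break
                d = _random_direction(rng)
                r_dir = _ellipsoid_radius(rec.semi_axes_um, d)
                pos = tuple(
                    rec.center_um[j] + d[j] * p.cc_radial_fraction * r_dir for j in range(3)
                )
                # keep the blob strictly inside the nucleus and off its siblings
                if p.cc_radial_fraction * r_dir + radius_um >= r_dir:
                    continue
                if all(math.dist(pos, q) > 2.5 * radius_um for q in centers):
                    centers.append(pos)
            if len(centers) < k:
                raise FixtureError(
                    f"could not place {k} domains of radius {radius_um} µm "
                    f"in a nucleus of semi-axes {rec.semi_axes_um} µm"
                )
            return centers

        if p.n_chromocenters:
            for pos in _blob_centers(p.n_chromocenters, p.cc_radius_um):
                blob = _ellipsoid_mask(shape, cal, pos, (p.cc_radius_um,) * 3)
                dna[blob & m] = rec.level * p.cc_intensity_ratio
                cc_labels[blob & m] = next_cc
                next_cc += 1
            rec.n_chromocenters = p.n_chromocenters

        if p.nucleolus:
            rn = p.nucleolus_radius_fraction * min(rec.semi_axes_um)
            # displaced within the XY plane: peripheral nucleoli of flattened
            # nuclei sit laterally, which is the geometry of the indentation
            # artifact (a bite open in every Z slice, immune to hole filling)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            d = np.array([math.cos(phi), math.sin(phi), 0.0])
            r_dir = _ellipsoid_radius(rec.semi_axes_um, d)
            off = (r_dir - rn) if p.nucleolus_tangent else 0.35 * r_dir
            pos = tuple(rec.center_um[j] + d[j] * off for j in range(3))
            void = _ellipsoid_mask(shape, cal, pos, (rn,) * 3)
            dna[void & m] = rec.level * p.nucleolus_level

        for name, k in p.fish_channels:
            for pos in _blob_centers(k, p.fish_radius_um):
                blob = _ellipsoid_mask(shape, cal, pos, (p.fish_radius_um,) * 3)
                fish_imgs[name][blob & m] = p.fish_level * rec.level
                fish_labels[name][blob & m] = next_fish[name]
                next_fish[name] += 1

    sigma_vox = (p.blur_sigma_um[2] / cal.z, p.blur_sigma_um[1] / cal.y, p.blur_sigma_um[0] / cal.x)
    channels = {"dna": dna, **fish_imgs}
    for name in channels:
        if any(s > 0 for s in sigma_vox):
            channels[name] = ndi.gaussian_filter(channels[name], sigma=sigma_vox)
        if p.noise_sd > 0:
            channels[name] = channels[name] + rng.normal(0.0, p.noise_sd, size=shape)

    domain_labels = {}
    if p.n_chromocenters:
        domain_labels["chromocenter"] = cc_labels
    domain_labels.update(fish_labels)

    stack = CalibratedStack(data=channels["dna"], calibration=cal, name=f"field_seed{seed}", channel="dna")
    return SyntheticField(
        stack=stack,
        channels=channels,
        nucleus_labels=labels,
        domain_labels=domain_labels,
        records=placed,
        params=p,
        seed=seed,
        metadata={"seed": seed},
    )


def make_bead_stack(
    diameter_um: float,
    calibration: Calibration = Calibration(0.103, 0.103, 0.2),
    n_beads: int = 7,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    blur_sigma_um: tuple[float, float, float] = (0.08, 0.08, 0.16),
    noise_sd: float = 0.005,
) -> SyntheticField:
    """Bead-like field: homogeneous spheres of a known physical diameter.

    Emulates fluorescent calibration microspheres (1 / 2.5 / 4 µm): spheres
    rasterized on the anisotropic grid, lightly blurred, placed without
    contact. Theoretical volume is reported in the metadata.
    """
    if diameter_um <= 0:
        raise FixtureError("bead diameter must be positive")
    cal = Calibration(*calibration).validate()
    radius = diameter_um / 2.0
    if shape is None:
        # one row of beads with a comfortable gap
        pitch_vox_x = int(math.ceil((diameter_um + 5.0) / cal.x))
        nx = pitch_vox_x * n_beads + 20
        ny = int(math.ceil((diameter_um + 5.0) / cal.y)) + 10
        nz = int(math.ceil((diameter_um + 2.0) / cal.z)) + 10
        shape = (nz, ny, nx)
    extent_um = (shape[2] * cal.x, shape[1] * cal.y, shape[0] * cal.z)
    if any(2 * radius + 1.0 >= ext for ext in extent_um):
        raise FixtureError(
            f"bead of diameter {diameter_um} µm does not fit stack extent {extent_um} µm"
        )
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)
    centers: list[tuple[float, float, float]] = []
    # beads sit in jittered slots along x, so any count fits reproducibly
    pitch = (extent_um[0] - 2 * (radius + 0.5)) / n_beads
    if pitch < diameter_um + 1.0:
        raise FixtureError(
            f"{n_beads} beads of {diameter_um} µm do not fit the stack extent {extent_um} µm"
        )
    jitter = max((pitch - diameter_um - 1.5) / 2.0, 0.0)
    for i in range(n_beads):
        cx = radius + 0.5 + (i + 0.5) * pitch + rng.uniform(-jitter, jitter)
        cy = rng.uniform(radius + 0.5, extent_um[1] - radius - 0.5)
        cz = rng.uniform(radius + 0.5, extent_um[2] - radius - 0.5)
        centers.append((cx, cy, cz))
        m = _ellipsoid_mask(shape, cal, centers[-1], (radius,) * 3)
        img[m] = 1.0
        labels[m] = i + 1
    sigma_vox = (blur_sigma_um[2] / cal.z, blur_sigma_um[1] / cal.y, blur_sigma_um[0] / cal.x)
    if any(s > 0 for s in sigma_vox):
        img = ndi.gaussian_filter(img, sigma=sigma_vox)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    stack = CalibratedStack(data=img, calibration=cal, name=f"beads_{diameter_um}um", channel="dna")
    theo_v = 4.0 / 3.0 * math.pi * radius**3
    records = [
        NucleusRecord(label=i + 1, center_um=c, semi_axes_um=(radius,) * 3, level=1.0)
        for i, c in enumerate(centers)
    ]
    return SyntheticField(
        stack=stack,
        channels={"dna": img},
        nucleus_labels=labels,
        domain_labels={},
        records=records,
        params=FieldParams(shape=shape, calibration=cal, n_nuclei=n_beads),
        seed=seed,
        metadata={
            "seed": seed,
            "diameter_um": diameter_um,
            "theoretical_volume_um3": theo_v,
            "theoretical_surface_um2": 4.0 * math.pi * radius**2,
        },
    )
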