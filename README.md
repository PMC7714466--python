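# nucmorph

3D morphometrics of cell nuclei from wide-field fluorescence stacks:
automatic extraction of single-nucleus crops from multi-nucleus images,
two complementary segmentation methods, a corrected surface-area
estimator, and quantification of intranuclear domains (chromocenters and
FISH signals).

Quantitative nuclear morphology — volume, surface area, flatness,
elongation — and chromatin organization readouts are central to studying
the nuclear periphery, e.g. in *Arabidopsis* mutants of the
nucleoskeleton, where nuclei become smaller and rounder and chromocenters
fuse. The bottleneck is throughput: a wide-field stack holds tens of
nuclei of very different brightness, so one global threshold cannot
segment them, and naive voxel-counting surface areas are badly biased.
`nucmorph` addresses both with a batch pipeline intended for people who
image whole-mount tissue and want per-nucleus tables they can feed to
their own statistics.

## What it computes

**Autocrop.** A global Otsu threshold locates objects; 26-connected
components above 1 µm³ each yield a bounding box padded by 20 voxels,
optionally merged at 50 % overlap. Outputs: per-object crops, a
tab-separated coordinate table, and a numbered, inverted Z-projection.
The table can be re-applied voxel-identically to other channels.

**Segmentation, two ways.** The *modified Otsu* method scans thresholds
around the per-crop Otsu value, fills interior holes (the unstained
nucleolus), and keeps the most spherical plausible mask. The *3D
gift-wrapping* method refines that mask with a distance-restricted convex
hull — a Jarvis march in which a hull edge is accepted only if shorter
than td = ½(3V/4π)^⅓ — applied slice-wise in XY, XZ and YZ and unioned.
It bridges nucleolus indentations that defeat thresholding, at the cost of
a slight volume increase. Unsegmentable crops are quarantined as
`bad_crop`.

**Surface area.** The exposed-voxel-face sum overestimates smooth
surfaces by a staircase factor approaching 3/2. The corrected estimator
weights each surface element (surfel) by n̂·ê, with normals from the
smoothed image gradient: area = Σ A_s·max(n̂·ê_s, 0). On digitized spheres
of radii 5–50 voxels the mean observed/theoretical ratio is 1.62 for the
face sum and 1.06 for the surfel sum.

**Shape and domains.** Volume, flatness √(λ₂/λ₃), elongation √(λ₁/λ₂)
(covariance eigenvalues of calibrated voxel coordinates), sphericity
36πV²/S³; chromocenter/FISH-signal counts, volumes and anisotropic
Euclidean distances to the nuclear envelope (NbCc, VCcMean, VCcTotal,
dCcBarycentreNE, dFishBorderNE, dFishBarycenterNE).

All test inputs are generated in silico by `nucmorph.fixtures` (digitized
spheres, multi-nucleus fields with ground truth, bead-like calibration
objects); no downloads are required.

## Worked example

Segment a digitized sphere of radius 20 voxels with both methods and
compile the morphometrics table:

```python
import numpy as np
from nucmorph import (SegmentationConfig, compile_metrics,
                      gift_wrap_segment, make_digitized_sphere,
                      modified_otsu_segment)

stack = make_digitized_sphere(20).as_stack()      # unit-voxel calibration
cfg = SegmentationConfig(max_volume_um3=1e12)     # bounds meant for µm-scale nuclei
otsu = modified_otsu_segment(stack, cfg)
gift = gift_wrap_segment(stack, otsu, cfg)
print(compile_metrics([otsu, gift]).round(3).to_string(index=False))
```

```
 Crop Method  Volume  SurfaceArea_initial  SurfaceArea_new  Sphericity  Sphericity_initial  Flatness  Elongation  EquivalentRadius
    0   otsu 36137.0               7878.0         5229.239       1.033               0.302       1.0         1.0            20.509
    0   gift 36137.0               7878.0         5229.239       1.033               0.302       1.0         1.0            20.509
```

Against the true sphere area 4π·20² = 5026.5, the face-sum column
(`SurfaceArea_initial`, 7878) carries the ×1.57 staircase inflation while
the surfel column (`SurfaceArea_new`, 5229) is within 4 %; sphericity
computed from the corrected area is ≈ 1, as it should be for a sphere,
versus 0.30 from the naive area. The sphere is convex, so gift-wrapping
reproduces the Otsu mask exactly.

## Command line

```
nucmorph autocrop STACKS_DIR --out out/ [--config run.cfg]
nucmorph autocrop STACK.tif --out out/ --coords coords.tsv --channels cy3.tif,cy5.tif
nucmorph segment out/crops --out seg/          # otsu/, gift/, bad_crop/, metrics.tsv
nucmorph domains --masks seg/gift --crops chromocenter=out/crops --out dom/
nucmorph fixtures --out fixtures/ --seed 1     # generate the synthetic suite
```

Configuration is a flat `key=value` file (`x_cal_um=0.103`,
`padding_voxels=20`, `min_volume_um3=1.0`, `merge_fraction=0.5`, ...);
see `nucmorph.config.RunConfig` for the full list and defaults.

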