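# Methods

`nucmorph` quantifies 3D nuclear morphology and intranuclear organization
from wide-field fluorescence stacks of DNA-stained tissue. This note
documents the models and procedures, the parameters that matter, what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was open.

## Autocrop

A wide-field stack contains tens of nuclei of heterogeneous brightness. A
single global Otsu threshold is only used to *locate* objects, never to
segment them: the stack intensities are rescaled onto 256 bins (so
thresholds are comparable across bit depths and acquisitions), the
between-class-variance-maximizing bin is taken, and 26-connected components
of the binary volume are measured in physical units. Components with volume
≤ `min_volume_um3` (default 1 µm³) are discarded; in plant material this
removes autofluorescent debris such as chloroplasts. Each surviving
component yields a bounding box expanded by `padding_voxels` (default 20)
in every direction and clamped to the stack. Optionally, boxes whose shared
voxel volume reaches `merge_fraction` (default 50 %) of the smaller box are
iteratively unioned to a fixed point — large nuclei can otherwise emit
several boxes. Products: per-object crops, a tab-separated coordinate table
(0-based origins, exclusive extents — lossless round-trip), and an
inverted maximum-intensity Z-projection with numbered box outlines for
visual curation. The same coordinate table can be re-applied voxel-
identically to other wavelength channels (FISH workflows).

Interpretation choices: "volume" filtering is volumetric (µm³), not a
diameter; box overlap is measured as 3D voxel volume against the smaller
box. Both are exposed in the configuration.

## Modified-Otsu segmentation

Each crop holds one nucleus whose grey-level range differs from its
neighbours', so the threshold is chosen per crop. Candidate thresholds are
scanned in a window of ±`threshold_window` bins (default 20 of 256) around
the plain Otsu value. At each candidate the largest 26-connected component
is kept and interior holes are filled — first slice-wise in Z, then in 3D —
because the nucleolus is unstained by DNA dyes and would otherwise puncture
the mask. Candidates outside plausible volume bounds
(`[min_volume_um3, max_volume_um3]`, default [0.5, 2000] µm³) are
discarded. Each candidate is scored by sphericity (36πV²/S³).

**Threshold choice.** The selected threshold is the candidate *nearest the
plain Otsu value* among those whose sphericity is within
`sphericity_tolerance` (default 2 %) of the scan optimum, rather than the
raw argmax. Rationale: on a blurred convex nucleus, sphericity increases
slowly but monotonically as the threshold drops (a dilated blurred
ellipsoid is marginally rounder), so the raw argmax slides to the window
edge and systematically inflates the volume by a fraction of the blur
width (~6 % in our recovery benchmark). The pathologies the scan exists to
rescue — a nucleus split by an over-bright chromocenter, or bitten by a
peripheral nucleolus — change sphericity by far more than 2 %, so the
rescue behaviour is unaffected while the drift disappears (median volume
error 4 % through the full pipeline).

A crop is classified `bad_crop` when no candidate passes the volume bounds
or the winning mask touches two opposing crop faces (truncated object).

## 3D gift-wrapping segmentation

The complementary, edge-based method refines the modified-Otsu mask. Its
primitive is a **distance-restricted convex hull** of a binary 2D slice: a
Jarvis-march (gift-wrapping) walk over the boundary pixels in exact integer
arithmetic, in which a hull edge is accepted only if its physical length is
at most a threshold distance *td*; where the spanning edge is longer, the
original object boundary is followed. Operationally: the full hull polygon
is rasterized by half-plane tests (degenerate hulls rasterize to exact
segment lattice points), pockets (hull minus filled object) are labelled,
and a pocket is bridged only if every hull edge adjacent to it is ≤ td.
Interior holes are always filled. With td = ∞ the primitive equals the
exact convex hull — this is tested against a brute-force
Carathéodory-membership oracle on random point sets.

*td* is half the radius of the volume-equivalent sphere of the input mask,
td = ½·(3V/4π)^⅓, so only concavities small relative to the nucleus are
bridged. It is measured in micrometres and converted per orientation with
the in-plane calibration, since the XZ and YZ planes are anisotropic.

The 3D method applies the primitive slice-by-slice in all three
orientations (XY, XZ, YZ), unites the three reconstructions with the input,
keeps the largest component and fills residual holes. The output therefore
always contains the input mask and never exceeds its 3D convex hull; on
convex digital objects it is idempotent and adds nothing. A result touching
two opposing crop faces is tagged `bad_crop`.

The method exists for one failure mode: a nucleolus close to the nuclear
periphery leaves a deep indentation that hole-filling cannot close (the
bite is open to the background). The restricted hull bridges its narrow
mouth in every slice while leaving genuinely elongated or flattened shapes
untouched. The cost is a slight volume increase, bounded in practice by the
rasterization slivers it closes (≤ 10 % on microsphere-like objects, and
0 on digitized spheres).

## Surface area

Two estimators are reported side by side.

**Exposed-face summation** (`SurfaceArea_initial`): every voxel face
between foreground and background contributes its full physical area. On a
smooth surface this counts the staircase, overestimating by a factor that
approaches 3/2 for a sphere (mean ratio 1.62 over digitized spheres of
radii 5–50).

**Surfel integration** (`SurfaceArea_new`): each exposed face contributes
its area scaled by max(n̂·ê, 0), where ê is the face direction and n̂ the
estimated outward unit normal. Normals are the central finite-difference
gradient of the raw image *f* (the mask itself when no intensity crop is
available), scaled by the anisotropic calibration, smoothed by
`smoothing_iterations` (default 2) rounds of box averaging restricted to
boundary voxels (an on-surface convolution), then normalized and
orientation-checked against the local foreground→background direction.
Voxels with a vanishing gradient fall back to full face weight. The surfel
sum is bounded above by the naive sum by construction. On the digitized
spheres the mean ratio to 4πr² is 1.065 with the default smoothing; the
default was chosen so this digital-sphere calibration holds.

## Digitized spheres

The reference objects are binary balls on an isotropic unit-voxel grid,
radii 5–50. The rasterization rule matters at these scales: the default
**midpoint rule** includes a voxel when its center lies within r + ½
(equivalently, rounded center distance ≤ r), so the cube faces of the
digital object straddle the nominal sphere of radius r; with it the two
estimators give mean area ratios 1.62 and 1.065 against 4πr². The strict
center rule (distance ≤ r) is available as an option
(`membership="center"`); it shifts both ratios down by roughly the
half-voxel shell (to 1.51 and 0.97), and is used where exact lattice-count
identities are wanted (e.g. 515 voxels at r = 5). Both rules are
enumerated against a brute-force lattice oracle in the tests.

## Shape parameters

Volume is the calibrated voxel sum. Flatness and elongation follow the
equivalent-ellipsoid radius-ratio convention: from eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ of the covariance of calibrated foreground coordinates,
elongation = √(λ₁/λ₂) and flatness = √(λ₂/λ₃); both 1 for a sphere, both
invariant to axis permutation, 90° rotation and uniform rescaling.
Sphericity 36πV²/S³ is computed against the surfel area (the corrected
estimator), with the naive-area variant also emitted for comparison.
Degenerate (coplanar/collinear) masks raise an error naming the nucleus.

## Intranuclear domains

Chromocenters (DNA-dye channel) and FISH signals (probe channels) are
bright foci inside a segmented nucleus. Their extent is a two-pass
contrast threshold: `contrast_factor` × mean nucleoplasm intensity, where
the nucleoplasm mean is re-estimated once after excluding the first-pass
foci (defaults: 1.5 for chromocenters, 2.0 for FISH channels, whose
off-signal background is darker). Foci merged into one super-threshold
component are split by a marker-based 3D watershed on the inverted
intensity; markers are the h-maxima of the super-threshold region
(`h_maxima_fraction`, default 0.1 of the intensity range above the
threshold), so a dumbbell with two intensity maxima splits at its neck
while a flat plateau stays one object. Domains below `min_volume_um3`
(default 0.02 µm³) are discarded. A threshold-component seed rule alone
cannot split merged foci — one component is one seed — hence the maxima
markers; the contrast rule still defines every domain's extent.

Distances to the nuclear envelope use the anisotropic Euclidean distance
transform of the nucleus mask (physical sampling, not voxel counts):
`d_border` is the minimum over the domain, `d_barycenter` the value at the
domain voxel nearest its volume barycenter — so border ≤ barycenter holds
by construction. Per-nucleus summaries report the count, mean and total
volume, and mean distances under the conventional column names (NbCc,
VCcMean, VCcTotal, dCcBarycentreNE; dFishBorderNE, dFishBarycenterNE).

## Synthetic data

The generator produces what the validation needs and nothing more:
ellipsoidal nuclei (axis-aligned, anisotropic grid, default calibration
XY 0.103 µm / Z 0.2 µm) with per-nucleus intensity levels, optional
chromocenter blobs at a configurable intensity ratio (default 3×) and
radial position (default 0.5 of the local radius), an optional nucleolus
modelled as an intensity well at 0.2× the nucleoplasm level — displaced
within the XY plane and optionally tangent to the envelope, which is the
geometry that defeats hole-filling and produces the indentation artifact —
anisotropic Gaussian blur, and additive Gaussian noise. Placement is
rejection-sampled with bounded retries; failure raises an error naming the
offending parameters. All randomness flows from one seed; identical
(parameters, seed) give bit-identical stacks.

Not emulated: a physical PSF (the blur is a separable Gaussian), optical
aberrations, depth-dependent attenuation, uneven illumination, or textured
chromatin. Passing tests therefore demonstrate algorithmic correctness on
idealized image formation, not robustness to every artifact of real
acquisitions.

Bead fixtures rasterize homogeneous spheres of known diameter (1 / 2.5 /
4 µm) in jittered slots on the anisotropic grid, with theoretical volume
and surface recorded in the metadata.

## Problem sizes and determinism

The validation suite uses six digitized spheres (radii 5–50), 50
single-nucleus fields for the growth/hull properties, 10 tangent-nucleolus
fixtures, five 10-nucleus fields for parameter recovery, and 12 fixtures
for domain quantification; these sizes give stable medians while keeping
the whole suite in a few minutes on one core. End-to-end runs are
deterministic: identical inputs, configuration and seed produce
byte-identical tables.

## Known limitations

* Gift-wrapping inflates volume slightly by design; use the Otsu mask when
  absolute volume matters and the object is well stained.
* The surfel estimator underestimates at sharp edges (smoothed normals tilt
  across creases), so box-like objects lose a few percent of their true
  area; for smooth biological shapes this is negligible.
* Domain splitting depends on distinct intensity maxima; foci merged
  without a detectable neck count as one.
* The watershed basins' extent is the super-threshold region; volumes are
  threshold-dependent, as in any contrast-based spot quantification.
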