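# Methods

This note documents the models, conventions and numerical choices behind
`femhead`. It is the authoritative description of *how* the package
computes what it computes; the README shows how to run it.

## Coordinate and intensity conventions

Volumes are indexed `data[x, y, z]` with isotropic voxel size in μm.
Anatomically +x is lateral, +y anterior, +z superior; "proximal" slices
are the highest z indices. Physical coordinates are voxel-centre
positions (`p = index × voxel_size`, 0-based). Intensities are 16-bit
unsigned grey-scale values (GSV); signed integer input is shifted into
this range with a logged warning, because the global bone threshold
(default 39,300 GSV) is only meaningful on the unsigned scale.
MetaImage/NIfTI spacings are interpreted as millimetres and converted;
TIFF requires an explicit voxel size.

## Pre-processing and segmentation

Noise is suppressed with a truncated discrete Gaussian (kernel
half-width `support = 3` voxels, `sigma = 1.2` voxels, renormalised to
unit sum, edge-replicated borders), followed by a global threshold.
The threshold comparison is `>=` — a voxel exactly at the threshold is
bone. The threshold is a configuration parameter: on real scans it is
chosen from the intensity histogram per study; phantoms use the
midpoint between their marrow and bone levels.

## Alignment to the mean trabecular direction

The head is rotated so the mean trabecular direction (MTD) lies along
the supero-inferior axis, and optionally so a fovea capitis landmark is
perpendicular to the antero-posterior axis (pointing medially, −x).
The MTD comes from the mean-intercept-length (MIL) fabric tensor:

* test lines at 1-voxel sampling steps and 3-voxel line spacing cover
  the region along `n_directions` (default 128) quasi-uniform
  orientations (Fibonacci hemisphere under a seeded random rotation);
* MIL(u) = bone length / number of bone runs along the lines
  (run-count convention; any fixed convention cancels in the
  anisotropy ratios);
* the ellipsoid `u'Mu = MIL(u)^-2` is fitted by linear least squares
  and eigen-decomposed; eigenvalues (sorted descending) are the MIL
  semi-axes, DA = 1 − λ3/λ1.

Two refinements matter in practice and are defaults:

* **Central ROI.** The fabric for alignment is estimated inside a
  central ball (60% of the bone extent) so the dense cortical shell
  does not dilute the trabecular signal.
* **Structure-tensor sharpening.** The angular resolution of intercept
  counting over ~10² directions is a few degrees, and for strongly
  oriented structures the MIL profile deviates from an ellipsoid near
  its cusp, biasing the fitted axis. When the fitted fabric is
  anisotropic (λ1/λ2 > 1.02), the principal direction is replaced by
  the eigenvector of the smallest eigenvalue of the gradient structure
  tensor Σ∇I∇Iᵀ of the smoothed occupancy field (gradients are
  perpendicular to rod-like structures), provided it corroborates the
  MIL axis within 15°. This resolves the axis to a fraction of a
  degree; MIL eigenvalues (and hence DA) are untouched.

The rotation is applied about the volume centre with linear
interpolation of the *raw* grey values, after which filtering and
segmentation are repeated — repositioning before filtering keeps
resampling aliasing out of the binarised structure. Masks are
resampled nearest-neighbour. If the estimated rotation is smaller than
the grid's angular resolution (about `atan(1/R)` for a head of radius
R voxels, ≈0.5° at R = 115), the volume is left untouched: such a
rotation cannot move any voxel by a full voxel but resampling measurably
erodes thin struts (see *Limitations*).

## Masks

**Whole-bone mask** — per axial slice: Euclidean-disk closing (radius
40 voxels) bridges trabecular porosity, then a shrink-wrap step —
closing with radius `bridge_gap/2` (default 15) followed by
exterior-complement hole filling — produces a solid silhouette that
bridges surface openings narrower than `bridge_gap` (30 px). Closing
is extensive, so the mask is always a superset of the segmented bone.

**Trabecular mask** — rasterised from sparse closed contours (drawn
every 25 axial sections in the reference protocol); intermediate slices
take the zero-superlevel set of the linearly interpolated signed
distance fields of the bracketing contours. Drawn slices are
reproduced voxel-exactly; slices outside the drawn range are empty.
When contours are auto-extracted from a reference mask (phantom
validation), midpoint slices are inserted recursively wherever the
cross-section area changes by more than 25% between drawn slices,
emulating the denser tracing an operator applies near the pole. For
validation phantoms the contour interval is also scaled to keep the
chord sag of the interpolation at the level of the reference protocol
(≈¼ voxel): sag grows as (interval)²/radius, and validation heads are
2–3× smaller than human femoral heads.

**Cortical mask** — Boolean `whole AND NOT trabecular`, restricted to
the most proximal `max_depth_slices` (default 257; ≈10 mm at 39 μm) so
distal osteophytes never enter cortical metrics. Containment of the
trabecular mask in the whole-bone mask is enforced with an error that
reports the violating voxel count. No island cleaning is applied to the
subtraction. A specimen whose cortex cannot be delineated is analysed
with an empty contour set: the whole bone is treated as trabecular and
plate metrics are reported missing.

## Head sphere and partition

The sphere is an algebraic least-squares fit to the outer surface
voxels (6-connectivity) of the mask. With `exclude_below_estimate`,
surface points below the current centre (with a one-voxel margin, so a
flat equatorial face cannot re-enter) are discarded and the fit
iterated; iteration stops when the centre moves < 0.5 voxel or the
exclusion set repeats (a cycle), with a hard cap of 50 iterations.
The fit is re-run on the trabecular mask so osteophytes on the outer
surface cannot displace the volumes of interest.

The analysis region is every trabecular voxel with z ≥ z_c and radial
distance ρ ≤ r. Layers (CTB/MTB/STB) are half-open thirds of the
radius, the outermost closed at r. Elevation is measured from the
transverse plane through the centre; the superior band is
φ_el ≥ π/4. Azimuth is zero at +y (anterior), counter-clockwise viewed
from superior, in half-open sectors of π/4; boundary voxels go to the
lower sector. The sector-to-name mapping (AAM, PAM, APM, PPM, PPL,
APL, PAL, AAL) follows from splitting each anatomical quadrant into its
anterior/posterior half; a `mirror_x` flag mirrors the medio-lateral
axis for contralateral femurs. This yields 5 macro regions (the
central layer is never band- or octant-split) plus 2 layers × 2 bands ×
8 octants = 32 sub-regions: 37 named VOIs, each voxel carrying exactly
one sub-label.

## Morphometric indices

* **BV/TV** (%) — bone voxels / VOI voxels.
* **Tb.Th, Tb.Sp, Pl.Th** (μm) — model-independent local thickness:
  the thickness at a voxel is the diameter of the largest sphere fully
  inside the phase that contains it. Implementation: Euclidean
  distance transform; candidate centres pruned when a 26-neighbour's
  inscribed sphere contains theirs (a pure pruning — the painted map is
  identical); remaining spheres painted in descending radius keeping
  the per-voxel maximum. The inscribed radius at a centre is
  EDT − 0.5 voxel, i.e. the distance to the phase boundary rather than
  to the nearest background voxel centre; an n-voxel slab then reads n
  voxels for odd n and n − 1 for even n, and a digital ball of radius
  10 reads 21 — all within the ±1 voxel quantisation inherent to
  digital thickness. Separation is the same measure on the background
  phase restricted to the trabecular mask, so cavities dominate its
  spread but tissue outside the mask never contributes. Statistics are
  taken over phase voxels inside each VOI while spheres may extend past
  the VOI boundary, avoiding edge truncation bias.
* **Tb.N** (mm⁻¹) — (BV/TV)/Tb.Th, so Tb.N × Tb.Th(mm) = BV/TV/100
  holds identically.
* **Conn.D** (mm⁻³) — (1 − χ)/VOI volume with χ the Euler
  characteristic at 26-connectivity for bone / 6 for background (a
  Jordan-consistent pair), computed after purification (largest
  26-connected component kept, enclosed cavities filled), so that
  1 − χ equals the number of redundant connections (β1). Purification
  can be disabled, in which case Conn.D is additive over disjoint
  structures up to the component count.
* **DA** — 1 − λ3/λ1 ∈ [0, 1] of the MIL fabric, 0 = isotropic.
  Reported for the whole trabecular region only; this convention is
  fixed here because it is the bounded one consistent with values
  reported for human femoral heads (≈0.4–0.5).
* **Pl.Th, Pl.Po** — mean local thickness of the bone phase inside the
  cortical mask, and the percentage of non-mineralised voxels in it,
  reported per azimuth octant (relative to the fitted centre) and
  overall. An empty cortical mask yields missing values, not an error.

## Cyst-candidate screening

A VOI is flagged when the standard deviation of its Tb.Sp is strictly
greater than 585 μm (configurable). Flagged VOIs with BV/TV below 10%
carry a `low_bvtv_note`: very sparse bone widens the separation spread
without any cavity, the screen's known false-positive mode. The screen
reports candidates for visual review; it does not declare cysts.

## The phantom generator

Validation runs on synthetic heads: a digital ball (default radius
7.5 mm at 60 μm ≈ 255³ voxels) with a dense shell (600 μm) around a
three-family rod lattice (primary rods along a configurable axis at
1.2 mm pitch, 300 μm diameter; transverse families at twice the pitch
for connectivity), optional spherical voids placed at named-region
centroids, an optional osteophyte-like surface bump, a known rigid
rotation applied to the generative geometry (no resampling), and
additive Gaussian GSV noise (seeded; bone/marrow separation must exceed
4× the noise SD). The surrounding medium defaults to the marrow
intensity, as for a specimen potted in soft-tissue-equivalent material;
this keeps the blurred outer shell boundary symmetric under the
midpoint threshold. Ground truth (masks, sphere, rotation, per-VOI
BV/TV) is computed from the generative geometry by exact counting; the
closed-form lattice fraction (inclusion–exclusion with orthogonal
cylinder crossings and the Steinmetz triple term) is retained as an
independent cross-check.

What the phantom does *not* emulate: curved and perforated trabeculae,
plate-like architecture, mineral density gradients, beam hardening and
cone-beam artefacts, or anatomically realistic osteophytes. Passing
phantom recovery therefore validates the geometry and measurement
chain, not scanner physics.

## Problem sizes used in validation

Unit fixtures are ≤ 32³ (where thickness is checked voxel-for-voxel
against an exhaustive pairwise-distance oracle); mid-size phantoms are
~67³ and ~171³; full-pipeline parameter recovery runs once at the
default ~255³ and cyst screening at ~197³. These sizes resolve every
structure by ≥ 3 voxels while keeping routine validation runs at
desk scale.

## Known limitations

* Resampling a volume whose struts are ~5 voxels thick erodes the
  inscribed-sphere thickness by up to 1–2 voxels at the "waists" the
  interpolation creates, even for sub-degree rotations; volume
  fraction is almost unaffected. This is intrinsic to rotating
  binarisable data near the resolution limit (real reconstructions
  carry the same effect at an unknown phase); it motivates the
  skip-below-grid-resolution rule in alignment.
* MIL direction estimates saturate at ~3° on perfectly straight
  volume-spanning rods (the on-axis intercept count is dominated by
  lines riding inside or between rods); the structure-tensor
  refinement exists for exactly this regime. The MIL eigenvalue *sum*
  is rotation-stable only for structures the ellipsoid model fits
  (mild anisotropy, DA ≲ 0.4); strongly cusped profiles violate it.
* Even-thickness digital plates read one voxel thin under the
  inscribed-sphere convention (see above); all reported thicknesses
  carry ±1 voxel quantisation.
* The shrink-wrap emulation (closing + exterior flood fill) reproduces
  the documented intent of the proprietary operation — bridge openings
  ≤ 30 px and fill enclosed holes — not its exact implementation.
* Osteophytes are handled only by the depth restriction and mask
  editing; they are not detected automatically. Group statistics are
  descriptive (median, IQR, min–max) by design.
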