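# femhead

Regional micro-architectural morphometry of the human femoral head from
microCT.

Whole-head microCT makes it possible to ask *where* a disease such as
osteoarthritis changes bone — not just whether it does. `femhead` takes a
grey-scale microCT volume of an excised femoral head and produces a
comprehensive regional map of its cortical and trabecular
micro-architecture: it segments the bone, aligns the head to its mean
trabecular direction, isolates the subchondral bone plate, fits a sphere
to the head, partitions the proximal hemisphere into **37 named volumes
of interest** in spherical coordinates, computes the standard
morphometric indices in every region, and screens for subchondral
bone-cyst candidates. A synthetic phantom generator with exact ground
truth makes the entire pipeline testable without scan data.

It is intended for researchers in bone biomechanics and skeletal
pathophysiology working with laboratory microCT of whole epiphyses.

## The method

1. **Pre-processing** — Gaussian filter (support 3 voxels, σ = 1.2),
   global threshold on the 16-bit grey scale (voxel is bone iff
   GSV ≥ threshold).
2. **Alignment** — the mean trabecular direction (principal eigenvector
   of the mean-intercept-length fabric tensor, sharpened by a gradient
   structure tensor) is rotated onto the supero-inferior axis;
   optionally the fovea capitis is set perpendicular to the
   antero-posterior axis.
3. **Masks** — per-slice closing (radius 40 voxels) + shrink-wrap
   (bridge openings ≤ 30 px, fill holes) give the whole-bone mask; the
   trabecular mask is interpolated between sparse manual contours
   (every 25 sections) via signed-distance blending; the cortical mask
   is their Boolean difference restricted to the most proximal 257
   slices (≈10 mm at 39 μm) so osteophytes stay out.
4. **Sphere and partition** — a least-squares sphere is fitted to the
   head surface (iteratively ignoring points below its centre) and
   re-fitted on the trabecular mask; the hemisphere above the centre is
   split into three equal-depth layers (CTB, MTB, STB), superior /
   inferior bands at elevation π/4, and eight azimuthal octants of
   width π/4 — 5 macro regions + 32 sub-regions = 37 VOIs.
5. **Morphometry per VOI** — BV/TV (%), Tb.Th and Tb.Sp (μm, local
   sphere-fitting, model-independent), Tb.N = (BV/TV)/Tb.Th (mm⁻¹),
   Conn.D = (1 − χ)/V (mm⁻³, Euler characteristic after purification),
   DA = 1 − λ3/λ1 (whole trabecular region), and for the plate Pl.Th
   (μm) and Pl.Po (%) per octant.
6. **Cyst screen** — VOIs with SD(Tb.Sp) > 585 μm are flagged for
   visual review; flags with BV/TV < 10% are annotated as the known
   sparse-bone false-positive mode.

Details, conventions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Generate a phantom head (4.8 mm radius, 0.6 mm shell, rod lattice of
300 μm struts at 1.2 mm pitch, 60 μm voxels, seeded noise) and run the
full pipeline against its own ground truth:

```python
import femhead as fh
from femhead.phantom import PhantomSpec, LatticeSpec, generate

spec = PhantomSpec(head_radius_um=4800, shell_thickness_um=600,
                   lattice=LatticeSpec(pitch_um=1200, element_thickness_um=300),
                   voxel_size_um=60, noise_sd=1500, seed=2)
vol, truth = generate(spec)

cfg = fh.RunConfig(threshold_gsv=spec.segmentation_threshold,
                   closing_radius=15, shrinkwrap_bridge=10, roi_spacing=9)
res = fh.run_pipeline(spec, config=cfg, out_dir="out",
                      trabecular_reference=truth.trabecular)

whole = res.regions[res.regions.kind == "all"].iloc[0]
plate = res.plate[res.plate.octant == "overall"].iloc[0]
bvtv_truth = 100 * (truth.bone.data & truth.trabecular.data).sum() / truth.trabecular.count()
print(f"BV/TV  {whole.BV_TV:.2f} %   (truth {bvtv_truth:.2f} %)")
print(f"Tb.Th  {whole.Tb_Th_mean:.0f} um  (truth {truth.tb_th_um:.0f} um)")
print(f"Pl.Th  {plate.Pl_Th:.0f} um  (truth {truth.pl_th_um:.0f} um)")
print(f"radius {res.sphere_trab.radius:.0f} um (truth {truth.sphere.radius - truth.pl_th_um:.0f} um)")
print(f"DA     {whole.DA:.2f}   flags {int(res.cysts.flagged.sum())}")
```

Output from this exact run:

```
BV/TV  7.31 %   (truth 7.39 %)
Tb.Th  276 um  (truth 300 um)
Pl.Th  544 um  (truth 600 um)
radius 4170 um (truth 4200 um)
DA     0.35   flags 0
```

The pipeline recovers the generative parameters within the digital
quantisation of each measure (thicknesses within one 60 μm voxel, the
sphere radius within half a voxel); the homogeneous lattice raises no
cyst flags. `out/regions.csv` holds one row per named VOI (37 trabecular
rows plus the whole-region row), `out/plate.csv` the per-octant plate
metrics, `out/cysts.csv` the screen, and `out/run_log.json` the full
configuration for reproduction.

The same pipeline runs from the shell on real scans:

```sh
femhead run-all scan.mha --out-dir out --contours contours.json
femhead summarize out_oa_*/regions.csv --out oa_summary.csv
```

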