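"""Cortical and trabecular micro-architectural indices.

All indices are model-independent, computed directly on the binary
volume:

* BV/TV (%) — bone voxels / VOI voxels.
* Tb.Th, Tb.Sp (μm) — local thickness of the bone / marrow phase by the
  local sphere-fitting method: the thickness at a voxel is the diameter
  of the largest sphere fully inside the phase that contains it
  (Euclidean distance transform, then maximal-sphere painting).
* Tb.N (mm^-1) — (BV/TV) / Tb.Th.
* Conn.D (mm^-3) — (1 - Euler characteristic) per VOI volume, after
  purification (largest 26-connected component, enclosed cavities
  filled); counts redundant trabecular connections (handles).
* DA — 1 - λ3/λ1 of the MIL fabric tensor (0 = isotropic), whole
  trabecular region only.
* Pl.Th (μm), Pl.Po (%) — local thickness of the subchondral plate and
  its non-mineralised voxel fraction, per azimuth octant and overall.

Digital conventions: the inscribed-sphere radius at a candidate centre
is EDT − 0.5 voxel (distance from the voxel centre to the phase
boundary, not to the nearest background voxel centre), so a slab of n
voxels reads n voxels thick.  Thickness statistics are taken over phase
voxels inside the VOI while spheres may extend past the VOI boundary.
Connectivity conventions are 26 for bone and 6 for background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .errors import ConsistencyError, DegenerateStructureError, EmptyRegionError
from .head_geometry import OCTANT_NAMES, RegionLabelMap
from .preprocess import FabricTensor
from .volume_io import BinaryVolume

logger = logging.getLogger(__name__)

__all__ = [
    "ThicknessMap",
    "bone_volume_fraction",
    "local_thickness",
    "trabecular_number",
    "connectivity_density",
    "degree_of_anisotropy",
    "plate_metrics",
    "summarize_regions",
]


@dataclass
class ThicknessMap:
    """Per-voxel local thickness (μm) defined on one phase; NaN elsewhere."""

    values: np.ndarray
    phase: str
    voxel_size: float

    def stats(self, voi: np.ndarray | None = None) -> tuple[float, float, int]:
        """(mean, SD, n) of the thickness over phase voxels inside voi."""
        v = self.values if voi is None else np.where(voi, self.values, np.nan)
        vals = v[np.isfinite(v)]
        if vals.size == 0:
            return float("nan"), float("nan"), 0
        return float(vals.mean()), float(vals.std()), int(vals.size)


def bone_volume_fraction(seg: BinaryVolume, voi: BinaryVolume | np.ndarray) -> float:
    """BV/TV (%): proportion of the VOI occupied by bone voxels."""
    voi_data = voi.data if isinstance(voi, BinaryVolume) else np.asarray(voi, bool)
    n_voi = int(voi_data.sum())
    if n_voi == 0:
        raise EmptyRegionError("VOI is empty")
    return 100.0 * int((seg.data & voi_data).sum()) / n_voi


_NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _ridge_centers(d: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Drop centres whose inscribed sphere a 26-neighbour's sphere contains.

    Ball(c, d(c)−½) ⊆ Ball(n, d(n)−½) iff d(n) − d(c) ≥ |n − c|, so such
    centres cannot change the painted maximum and are removed.  This is
    a pure pruning: the surviving set paints the identical thickness map.
    """
    keep = phase.copy()
    for off in _NEIGHBOURS_26:
        norm = np.sqrt(sum(o * o for o in off))
        sl_src = tuple(slice(max(o, 0), n + min(o, 0)) for o, n in zip(off, d.shape))
        sl_dst = tuple(slice(max(-o, 0), n + min(-o, 0)) for o, n in zip(off, d.shape))
        dominated = d[sl_src] - d[sl_dst] >= norm + 1e-9
        keep[sl_dst] &= ~dominated
    return keep & phase


def _ball_footprint(rv: float) -> np.ndarray:
    n = int(np.ceil(rv))
    ax = np.arange(-n, n + 1, dtype=np.float32)
    return (ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
            <= rv * rv + 1e-6)


def _paint_thickness(phase: np.ndarray) -> np.ndarray:
    """Local thickness in voxel units on a boolean phase array.

    EDT gives each candidate centre its inscribed-sphere radius
    d − 0.5; non-maximal centres are pruned (sphere contained in a
    neighbour's), the rest are processed by descending radius and their
    spheres painted into the map, keeping the maximum diameter at every
    covered voxel.
    """
    d = ndi.distance_transform_edt(phase)
    th = np.zeros(phase.shape, np.float32)
    centers_mask = _ridge_centers(d, phase)
    padded = None
    shape = np.array(phase.shape)
    uniq = np.unique(d[centers_mask])
    pad = int(np.ceil(float(uniq.max()) - 0.5)) + 1 if uniq.size else 1
    padded = np.zeros(tuple(shape + 2 * pad), np.float32)
    inner = tuple(slice(pad, pad + s) for s in shape)
    for dv in uniq[::-1]:
        rv = float(dv) - 0.5
        diam = np.float32(2.0 * rv if rv > 0 else 1.0)
        idx = np.argwhere(centers_mask & (d == dv))
        fp = _ball_footprint(max(rv, 0.0))
        n = fp.shape[0] // 2
        view = padded
        for x, y, z in idx:
            sl = (slice(x + pad - n, x + pad + n + 1),
                  slice(y + pad - n, y + pad + n + 1),
                  slice(z + pad - n, z + pad + n + 1))
            region = view[sl]
            np.maximum(region, np.where(fp, diam, 0), out=region)
    th = padded[inner]
    th[~phase] = 0
    return th


def local_thickness(
    mask: BinaryVolume,
    phase: str = "bone",
    voi: BinaryVolume | np.ndarray | None = None,
) -> ThicknessMap:
    """Local sphere-fitting thickness map of one phase.

    ``phase='bone'`` measures the mask itself (Tb.Th / Pl.Th);
    ``phase='background'`` measures its complement (Tb.Sp), restricted
    to ``voi`` when given so that structures outside the analysis mask
    do not contribute.  Spheres are fitted in the full phase; ``voi``
    restricts which voxels belong to the phase, not the sphere extent.
    """
    if phase not in ("bone", "background"):
        raise ValueError(f"phase must be 'bone' or 'background', got {phase!r}")
    ph = mask.data if phase == "bone" else ~mask.data
    if voi is not None:
        voi_data = voi.data if isinstance(voi, BinaryVolume) else np.asarray(voi, bool)
        ph = ph & voi_data
    if not ph.any():
        raise EmptyRegionError(f"{phase} phase is empty")
    th_vox = _paint_thickness(ph)
    values = np.where(ph, th_vox * mask.voxel_size, np.nan).astype(np.float32)
    return ThicknessMap(values=values, phase=phase, voxel_size=mask.voxel_size)


def trabecular_number(bv_tv: float, tb_th_mean_um: float) -> float:
    """Tb.N (mm^-1): fractional volume divided by mean thickness."""
    if not tb_th_mean_um > 0 or not np.isfinite(tb_th_mean_um):
        warnings.warn("zero or undefined Tb.Th; Tb.N is undefined", stacklevel=2)
        return float("nan")
    return (bv_tv / 100.0) / (tb_th_mean_um / 1000.0)


def _purify(bone: np.ndarray) -> np.ndarray:
    """Largest 26-connected bone component with enclosed cavities filled."""
    if not bone.any():
        return bone
    lab, n = ndi.label(bone, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        bone = lab == counts.argmax()
    # fill cavities: 6-connected background components not touching the border
    bg_lab, nbg = ndi.label(~bone, structure=ndi.generate_binary_structure(3, 1))
    border = np.zeros_like(bone)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    outside = np.unique(bg_lab[border & ~bone])
    cavity = ~bone & ~np.isin(bg_lab, outside)
    return bone | cavity


def connectivity_density(
    seg: BinaryVolume, voi: BinaryVolume | np.ndarray, purify: bool = True
) -> float:
    """Conn.D (mm^-3): (1 − Euler characteristic) per VOI volume.

    The Euler characteristic is computed with 26-connectivity on the
    (optionally purified) bone inside the VOI; after purification
    β0 = 1 and β2 = 0, so 1 − χ equals the number of redundant
    connections (handles, β1).
    """
    voi_data = voi.data if isinstance(voi, BinaryVolume) else np.asarray(voi, bool)
    n_voi = int(voi_data.sum())
    if n_voi == 0:
        raise EmptyRegionError("VOI is empty")
    bone = seg.data & voi_data
    if not bone.any():
        warnings.warn("no bone in VOI; Conn.D = 0", stacklevel=2)
        return 0.0
    ii = np.argwhere(bone)
    lo = np.maximum(ii.min(axis=0) - 1, 0)
    hi = ii.max(axis=0) + 2
    sub = np.pad(bone[tuple(slice(a, b) for a, b in zip(lo, hi))], 1)
    if purify:
        sub = _purify(sub)
    chi = measure.euler_number(sub, connectivity=3)
    vol_mm3 = n_voi * (seg.voxel_size / 1000.0) ** 3
    return (1.0 - chi) / vol_mm3


def degree_of_anisotropy(fabric: FabricTensor) -> float:
    """DA = 1 − λ3/λ1 (0 = isotropic, →1 = fully oriented)."""
    lam = fabric.eigenvalues
    if lam[0] <= 0:
        raise DegenerateStructureError("degenerate fabric tensor (λ1 <= 0)")
    return float(1.0 - lam[2] / lam[0])


def _octant_index(
    shape: tuple[int, int, int], center_vox: np.ndarray, mirror_x: bool = False
) -> np.ndarray:
    """Azimuth octant (0..7, order of OCTANT_NAMES) of every voxel."""
    xi = np.arange(shape[0], dtype=np.float32)[:, None, None] - center_vox[0]
    yi = np.arange(shape[1], dtype=np.float32)[None, :, None] - center_vox[1]
    if mirror_x:
        xi = -xi
    az = np.mod(np.arctan2(-xi, yi), 2 * np.pi)
    k = np.minimum((az / (np.pi / 4)).astype(np.int8), 7)
    return np.broadcast_to(k, shape)


def plate_metrics(
    cortical: BinaryVolume,
    seg: BinaryVolume,
    octants: RegionLabelMap,
    mirror_x: bool = False,
) -> pd.DataFrame:
    """Subchondral-plate thickness and porosity, per azimuth octant and overall.

    Pl.Th is the mean local thickness of the bone phase inside the
    cortical mask; Pl.Po the percentage of non-mineralised voxels in
    the mask.  An empty cortical mask yields a table of missing values
    (the specimen is still analysable as trabecular bone).
    """
    rows = []
    names = list(OCTANT_NAMES) + ["overall"]
    if cortical.count() == 0:
        logger.warning("empty cortical mask; plate metrics reported missing")
        for name in names:
            rows.append(dict(octant=name, Pl_Th=np.nan, Pl_Th_sd=np.nan,
                             Pl_Po=np.nan, voxel_count=0))
        return pd.DataFrame(rows)
    th = local_thickness(
        BinaryVolume(seg.data & cortical.data, seg.voxel_size), phase="bone"
    )
    center_vox = octants.sphere.center / cortical.voxel_size
    k = _octant_index(cortical.shape, center_vox, mirror_x=mirror_x)
    for i, name in enumerate(OCTANT_NAMES):
        sel = cortical.data & (k == i)
        n = int(sel.sum())
        if n == 0:
            rows.append(dict(octant=name, Pl_Th=np.nan, Pl_Th_sd=np.nan,
                             Pl_Po=np.nan, voxel_count=0))
            continue
        po = 100.0 * int((sel & ~seg.data).sum()) / n
        mean, sd, _ = th.stats(sel)
        rows.append(dict(octant=name, Pl_Th=mean, Pl_Th_sd=sd, Pl_Po=po, voxel_count=n))
    n = cortical.count()
    po = 100.0 * int((cortical.data & ~seg.data).sum()) / n
    mean, sd, _ = th.stats(cortical.data)
    rows.append(dict(octant="overall", Pl_Th=mean, Pl_Th_sd=sd, Pl_Po=po, voxel_count=n))
    return pd.DataFrame(rows)


def summarize_regions(
    seg: BinaryVolume,
    labels: RegionLabelMap,
    th_bone: ThicknessMap,
    th_background: ThicknessMap,
    fabric: FabricTensor | None = None,
) -> pd.DataFrame:
    """Per-VOI morphometry table: one row per named VOI plus a whole-region row.

    Columns: name, kind, layer, band, octant, voxel_count, volume_mm3,
    BV_TV, Tb_Th_mean, Tb_Th_sd, Tb_Sp_mean, Tb_Sp_sd, Tb_N, Conn_D, DA.
    DA applies to the whole trabecular region only and is reported on
    the ``trabecular-all`` row.
    """
    if seg.shape != labels.labels.shape:
        raise ConsistencyError("segmentation and label map differ in shape")
    rows = []
    analysis = labels.labels > 0
    da = degree_of_anisotropy(fabric) if fabric is not None else np.nan
    regions = [("trabecular-all", "all", "n/a", "n/a", "n/a", analysis)]
    for _, r in labels.table.iterrows():
        regions.append(
            (r["name"], r["kind"], r["layer"], r["band"], r["octant"],
             np.isin(labels.labels, list(r["labels"])))
        )
    for name, kind, layer, band, octant, voi in regions:
        n = int(voi.sum())
        if n == 0:
            logger.warning("region %s is empty; metrics missing", name)
            rows.append(dict(name=name, kind=kind, layer=layer, band=band,
                             octant=octant, voxel_count=0))
            continue
        bvtv = bone_volume_fraction(seg, voi)
        th_mean, th_sd, _ = th_bone.stats(voi)
        sp_mean, sp_sd, _ = th_background.stats(voi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tbn = trabecular_number(bvtv, th_mean)
        connd = connectivity_density(seg, voi)
        rows.append(
            dict(
                name=name, kind=kind, layer=layer, band=band, octant=octant,
                voxel_count=n, volume_mm3=n * (seg.voxel_size / 1000.0) ** 3,
                BV_TV=bvtv, Tb_Th_mean=th_mean, Tb_Th_sd=th_sd,
                Tb_Sp_mean=sp_mean, Tb_Sp_sd=sp_sd, Tb_N=tbn, Conn_D=connd,
                DA=da if name == "trabecular-all" else np.nan,
            )
        )
    return pd.DataFrame(rows)
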