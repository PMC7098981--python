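"""Head sphere fitting and the 37-VOI spherical partition.

A sphere is least-squares fitted to the outer surface of the whole-bone
mask (optionally iterating with points below the current centre excluded,
so the femoral neck and osteophytes do not bias the fit) and re-fitted on
the trabecular mask.  The proximal hemisphere above the centre is then
partitioned in spherical coordinates into

* three depth layers of one third of the fitted radius each — central
  (CTB), middle (MTB) and subchondral (STB) trabecular bone;
* superior / inferior bands split at elevation pi/4 (MTB and STB only);
* eight azimuthal octants of width pi/4 (MTB and STB only), named
  anatomically (AAM, PAM, APM, PPM, PPL, APL, PAL, AAL).

That yields 5 macro regions (CTB, MTB-inf/sup, STB-inf/sup) plus
2 layers x 2 bands x 8 octants = 32 sub-regions: 37 named VOIs.

Angle conventions: elevation is measured from the transverse plane
through the sphere centre; azimuth is measured in the transverse plane
from +y (anterior), counter-clockwise when viewed from superior (+x is
lateral, so the sweep runs anterior -> medial -> posterior -> lateral).
Sectors are half-open ``[k*pi/4, (k+1)*pi/4)``; layer bounds are
half-open except the outermost, which closes at the fitted radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ConvergenceError, DegenerateStructureError, GeometryError
from .volume_io import BinaryVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SphereFit",
    "RegionLabelMap",
    "OCTANT_NAMES",
    "fit_sphere",
    "refit_on_trabecular",
    "partition",
]

#: Octant names in azimuthal order (sector k covers [k*pi/4, (k+1)*pi/4)).
#: Each anatomical quadrant (antero-medial, postero-medial, postero-lateral,
#: antero-lateral) is split into the half nearer the anterior or posterior
#: axis, giving the A*/P* prefix.
OCTANT_NAMES = ("AAM", "PAM", "APM", "PPM", "PPL", "APL", "PAL", "AAL")

LAYER_NAMES = ("CTB", "MTB", "STB")
BAND_NAMES = ("inf", "sup")


@dataclass
class SphereFit:
    """Least-squares head sphere: centre and radius in physical μm."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int = 0

    def center_voxels(self, voxel_size: float) -> np.ndarray:
        return self.center / voxel_size

    def radius_voxels(self, voxel_size: float) -> float:
        return self.radius / voxel_size


@dataclass
class RegionLabelMap:
    """Per-voxel VOI labels plus the label -> anatomical-name table.

    Voxel labels: 0 outside the analysis region, 1 = CTB, 2..33 the 32
    sub-regions.  ``table`` holds 37 rows (5 macro + 32 sub) with columns
    name, kind, layer, band, octant, labels (member label ids),
    voxel_count, volume_mm3.
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size: float = 1.0
    sphere: SphereFit | None = None

    def region_mask(self, name: str) -> np.ndarray:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"unknown region {name!r}")
        members = row.iloc[0]["labels"]
        return np.isin(self.labels, list(members))

    @property
    def sub_table(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == "sub"]

    @property
    def macro_table(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == "macro"]


def _surface_points(mask: np.ndarray) -> np.ndarray:
    """Outer-surface voxel indices: mask voxels 6-adjacent to background."""
    eroded = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(mask & ~eroded)


def _lsq_sphere(pts: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere through points (rows)."""
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    r = float(np.sqrt(sol[3] + (c**2).sum()))
    resid = np.linalg.norm(pts - c, axis=1) - r
    return c, r, float(np.sqrt((resid**2).mean()))


def fit_sphere(
    mask: BinaryVolume,
    exclude_below_estimate: bool = False,
    max_iter: int = 50,
    tol_voxels: float = 0.5,
) -> SphereFit:
    """Fit a sphere to the outer surface of a head mask.

    With ``exclude_below_estimate``, surface points below the current
    centre estimate (z < z_c) are discarded and the fit iterated until
    the centre moves less than half a voxel, so the distal neck and
    osteophyte surfaces do not bias the head sphere.
    """
    vs = mask.voxel_size
    pts_vox = _surface_points(mask.data)
    if len(pts_vox) < 50:
        raise DegenerateStructureError(
            f"only {len(pts_vox)} surface points; need at least 50 for a sphere fit"
        )
    pts = pts_vox.astype(float)
    c, r, rms = _lsq_sphere(pts)
    used = pts
    if exclude_below_estimate:
        seen: set[bytes] = set()
        for _ in range(max_iter):
            # one-voxel margin: surface points exactly at the equatorial
            # plane (e.g. a flat resection face) must not re-enter the fit
            keep = pts[:, 2] >= c[2] + 1.0
            if keep.sum() < 50:
                raise DegenerateStructureError(
                    "exclusion left fewer than 50 surface points"
                )
            # a repeated exclusion set means the iteration has entered a
            # cycle; the fit cannot improve further
            key = np.packbits(keep).tobytes()
            if key in seen:
                break
            seen.add(key)
            used = pts[keep]
            c_new, r, rms = _lsq_sphere(used)
            shift = np.linalg.norm(c_new - c)
            c = c_new
            if shift < tol_voxels:
                break
        else:
            raise ConvergenceError(
                f"sphere fit did not converge in {max_iter} iterations"
            )
    return SphereFit(center=c * vs, radius=r * vs, rms_residual=rms * vs, n_points=len(used))


def refit_on_trabecular(trab: BinaryVolume, **kwargs) -> SphereFit:
    """Re-run the sphere fit on the trabecular mask.

    Centres the VOIs on the trabecular bone so osteophytes attached to
    the outer surface cannot displace the partition.
    """
    return fit_sphere(trab, **kwargs)


def _build_table(labels: np.ndarray, voxel_size: float) -> pd.DataFrame:
    rows = []
    counts = np.bincount(labels.ravel(), minlength=34)
    vox_mm3 = (voxel_size / 1000.0) ** 3

    def add(name, kind, layer, band, octant, members):
        n = int(sum(counts[m] for m in members))
        rows.append(
            dict(
                name=name, kind=kind, layer=layer, band=band, octant=octant,
                labels=tuple(members), voxel_count=n, volume_mm3=n * vox_mm3,
            )
        )

    add("CTB", "macro", "CTB", "n/a", "n/a", [1])
    for li, layer in ((1, "MTB"), (2, "STB")):
        for bi, band in enumerate(BAND_NAMES):
            base = 2 + (li - 1) * 16 + bi * 8
            add(f"{layer}-{band}", "macro", layer, band, "n/a", list(range(base, base + 8)))
    for li, layer in ((1, "MTB"), (2, "STB")):
        for bi, band in enumerate(BAND_NAMES):
            base = 2 + (li - 1) * 16 + bi * 8
            for k, oct_name in enumerate(OCTANT_NAMES):
                add(f"{layer}-{band}-{oct_name}", "sub", layer, band, oct_name, [base + k])
    return pd.DataFrame(rows)


def partition(
    trab: BinaryVolume,
    sphere: SphereFit,
    elevation_split: float = np.pi / 4,
    azimuth_width: float = np.pi / 4,
    mirror_x: bool = False,
) -> RegionLabelMap:
    """Partition the proximal trabecular hemisphere into the 37 named VOIs.

    The analysis region is every trabecular voxel with z >= z_c and
    radial distance rho <= r_sphere.  ``mirror_x`` flips the
    medio-lateral axis before naming, for contralateral femurs.
    """
    vs = trab.voxel_size
    c = sphere.center / vs
    r = sphere.radius / vs
    shape = trab.shape
    if not all(-0.5 <= c[i] <= shape[i] - 0.5 for i in range(3)):
        raise GeometryError(f"sphere centre {c} (voxels) lies outside the volume")
    if r <= 0:
        raise GeometryError("sphere radius must be positive")

    idx = np.argwhere(trab.data)
    rel = idx - c
    rho = np.linalg.norm(rel, axis=1)
    in_region = (rel[:, 2] >= 0) & (rho <= r)
    if not in_region.any():
        raise GeometryError("no trabecular voxels above the sphere centre")
    rel = rel[in_region]
    rho = rho[in_region]
    idx = idx[in_region]

    layer = np.digitize(rho, [r / 3.0, 2.0 * r / 3.0])  # 0 CTB, 1 MTB, 2 STB
    sin_elev = np.divide(rel[:, 2], rho, out=np.ones_like(rho), where=rho > 0)
    elev = np.arcsin(np.clip(sin_elev, -1, 1))  # centre voxel counts as zenith
    band = (elev >= elevation_split).astype(int)  # 0 inf, 1 sup

    x = -rel[:, 0] if mirror_x else rel[:, 0]
    az = np.mod(np.arctan2(-x, rel[:, 1]), 2 * np.pi)
    octant = np.minimum((az / azimuth_width).astype(int), 7)

    labels_flat = np.where(
        layer == 0, 1, 2 + (layer - 1) * 16 + band * 8 + octant
    )
    labels = np.zeros(shape, np.int32)
    labels[idx[:, 0], idx[:, 1], idx[:, 2]] = labels_flat
    table = _build_table(labels, vs)
    return RegionLabelMap(labels=labels, table=table, voxel_size=vs, sphere=sphere)
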