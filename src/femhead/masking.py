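"""Whole-bone, trabecular and cortical mask construction.

The whole-bone mask is a per-slice solid silhouette of the segmented
bone: 2D morphological closing bridges trabecular porosity, then a
shrink-wrap step (a second closing that stretches over surface openings
up to ``bridge_gap`` pixels, followed by hole filling) produces a solid
cross-section.  The trabecular mask is interpolated between sparse
manually drawn contours; the cortical mask is their Boolean difference
restricted to the most proximal slices so distal osteophytes never enter
the cortical VOIs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyMaskError, InsufficientInputError, MaskConsistencyError
from .volume_io import BinaryVolume

logger = logging.getLogger(__name__)

__all__ = [
    "SliceROISet",
    "whole_bone_mask",
    "interpolate_trabecular_mask",
    "cortical_mask",
    "rois_from_mask",
]


@dataclass
class SliceROISet:
    """Sparse per-slice closed contours delineating the trabecular region.

    ``entries`` maps z-slice index -> list of polygons, each an (N, 2)
    array of (x, y) voxel coordinates.  Slice indices must be strictly
    increasing; the nominal drawing interval is every 25 axial sections.
    """

    entries: list[tuple[int, list[np.ndarray]]]
    spacing_slices: int = 25

    def __post_init__(self) -> None:
        zs = [z for z, _ in self.entries]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise InsufficientInputError("drawn slice indices must be strictly increasing")

    @classmethod
    def from_json(cls, path) -> "SliceROISet":
        raw = json.loads(Path(path).read_text())
        entries = [
            (int(e["slice"]), [np.asarray(p, float) for p in e["polygons"]])
            for e in raw["entries"]
        ]
        return cls(entries=entries, spacing_slices=int(raw.get("spacing_slices", 25)))

    def to_json(self, path) -> None:
        raw = {
            "spacing_slices": self.spacing_slices,
            "entries": [
                {"slice": z, "polygons": [p.tolist() for p in polys]}
                for z, polys in self.entries
            ],
        }
        Path(path).write_text(json.dumps(raw))


def _disk_closing(slice2d: np.ndarray, radius: float) -> np.ndarray:
    """Exact Euclidean-disk closing of a 2D mask via two distance transforms."""
    if radius <= 0:
        return slice2d.copy()
    pad = int(np.ceil(radius)) + 1
    s = np.pad(slice2d, pad)
    dil = ndi.distance_transform_edt(~s) <= radius
    ero = ndi.distance_transform_edt(dil) > radius  # erode the dilation back
    closed = ero | s  # closing is extensive; union guards boundary voxels
    return closed[pad:-pad, pad:-pad]


def _shrink_wrap(slice2d: np.ndarray, bridge_gap: float) -> np.ndarray:
    """Solid silhouette: bridge openings narrower than bridge_gap, fill holes."""
    bridged = _disk_closing(slice2d, bridge_gap / 2.0)
    return ndi.binary_fill_holes(bridged)


def whole_bone_mask(
    seg: BinaryVolume, closing_radius: float = 40, bridge_gap: float = 30
) -> BinaryVolume:
    """Solid per-slice silhouette of the segmented bone.

    Per axial slice: disk closing of radius ``closing_radius`` voxels,
    then shrink-wrap (closing of radius ``bridge_gap/2`` + hole filling).
    """
    if seg.count() == 0:
        raise EmptyMaskError("segmentation is empty; cannot build a whole-bone mask")
    out = np.zeros_like(seg.data)
    for z in range(seg.shape[2]):
        s = seg.data[:, :, z]
        if not s.any():
            continue
        closed = _disk_closing(s, closing_radius)
        out[:, :, z] = _shrink_wrap(closed, bridge_gap)
    return seg.copy_with(out | seg.data)


def _rasterise(polys: list[np.ndarray], shape_xy: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon2mask

    m = np.zeros(shape_xy, bool)
    for p in polys:
        m |= polygon2mask(shape_xy, p)
    return m


def _sdf(mask2d: np.ndarray) -> np.ndarray:
    """Signed distance: positive inside, negative outside; mask == (sdf > 0)."""
    inside = ndi.distance_transform_edt(mask2d)
    outside = ndi.distance_transform_edt(~mask2d)
    return inside - outside


def interpolate_trabecular_mask(
    rois: SliceROISet, shape: tuple[int, int, int]
) -> BinaryVolume:
    """Interpolate sparse drawn contours into a full trabecular mask.

    Drawn slices are rasterised exactly; intermediate slices take the
    zero-superlevel set of the linearly blended signed distance fields of
    the two bracketing drawn slices.  Slices outside the drawn range are
    empty.  Voxel size is attached by the caller.
    """
    if len(rois.entries) < 2:
        raise InsufficientInputError("need at least two drawn slices to interpolate")
    nz = shape[2]
    for z, _ in rois.entries:
        if not 0 <= z < nz:
            raise InsufficientInputError(f"drawn slice {z} outside volume (nz={nz})")
    out = np.zeros(shape, bool)
    drawn = [(z, _rasterise(polys, shape[:2])) for z, polys in rois.entries]
    for z, m in drawn:
        out[:, :, z] = m
    for (z0, m0), (z1, m1) in zip(drawn, drawn[1:]):
        if z1 - z0 < 2:
            continue
        s0, s1 = _sdf(m0), _sdf(m1)
        for z in range(z0 + 1, z1):
            w = (z - z0) / (z1 - z0)
            out[:, :, z] = ((1 - w) * s0 + w * s1) > 0
    return BinaryVolume(data=out, voxel_size=1.0)


def rois_from_mask(
    mask: BinaryVolume, spacing: int = 25, max_area_ratio: float = 1.25
) -> SliceROISet:
    """Extract drawn-slice contours from a reference trabecular mask.

    Emulates manual contouring: the first and last non-empty slices plus
    every ``spacing``-th slice in between are traced with sub-pixel
    iso-contours.  Where the cross-section changes rapidly between two
    drawn slices (area ratio above ``max_area_ratio`` — near the pole of
    the head, where a careful operator draws more densely), midpoint
    slices are added recursively.
    """
    from skimage import measure

    nz = mask.shape[2]
    nonempty = [z for z in range(nz) if mask.data[:, :, z].any()]
    if not nonempty:
        raise EmptyMaskError("mask is empty; no contours to extract")
    z0, z1 = nonempty[0], nonempty[-1]
    zs = sorted(set(list(range(z0, z1 + 1, spacing)) + [z1]))
    areas = {z: int(mask.data[:, :, z].sum()) for z in zs}
    stack = list(zip(zs, zs[1:]))
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        lo, hi = sorted((max(areas[a], 1), max(areas[b], 1)))
        if hi / lo <= max_area_ratio:
            continue
        mid = (a + b) // 2
        areas[mid] = int(mask.data[:, :, mid].sum())
        stack += [(a, mid), (mid, b)]
    zs = sorted(areas)
    entries = []
    for z in zs:
        s = mask.data[:, :, z].astype(float)
        if not s.any():
            continue
        contours = measure.find_contours(np.pad(s, 1), 0.5)
        polys = [c - 1.0 for c in contours if len(c) >= 3]
        if polys:
            entries.append((z, polys))
    return SliceROISet(entries=entries, spacing_slices=spacing)


def cortical_mask(
    whole: BinaryVolume, trab: BinaryVolume, max_depth_slices: int = 257
) -> BinaryVolume:
    """Boolean subtraction whole AND NOT trabecular, restricted in depth.

    Only the most proximal (highest-z) ``max_depth_slices`` slices are
    kept, so distal osteophytes are excluded from cortical metrics.
    """
    if whole.shape != trab.shape:
        raise MaskConsistencyError("whole and trabecular masks differ in shape")
    viol = int((trab.data & ~whole.data).sum())
    if viol:
        raise MaskConsistencyError(
            f"trabecular mask extends outside the whole-bone mask at {viol} voxels",
            violating_voxels=viol,
        )
    cort = whole.data & ~trab.data
    nz = whole.shape[2]
    cut = max(0, nz - max_depth_slices)
    if cut:
        cort = cort.copy()
        cort[:, :, :cut] = False
    return whole.copy_with(cort)


def restriction_depth_mm(max_depth_slices: int, voxel_size_um: float) -> float:
    """Physical depth (mm) covered by the cortical slice restriction."""
    return max_depth_slices * voxel_size_um / 1000.0
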