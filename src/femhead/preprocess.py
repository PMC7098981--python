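"""Denoising, segmentation and alignment to the mean trabecular direction.

The raw reconstruction is smoothed with a small truncated Gaussian,
binarised with a global grey-scale threshold, and rigidly rotated so
that the mean trabecular direction (MTD) — the principal eigenvector of
the mean-intercept-length (MIL) fabric tensor — lies along the
supero-inferior (+z) axis.  Optionally a fovea capitis landmark is then
rotated about z until it is perpendicular to the antero-posterior (+y)
axis, fixing the azimuthal orientation of the head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateStructureError, GeometryError, ParameterError
from .volume_io import BinaryVolume, ScalarVolume

logger = logging.getLogger(__name__)

__all__ = [
    "FabricTensor",
    "RigidTransform",
    "denoise",
    "segment",
    "estimate_fabric",
    "align",
    "apply_transform",
]


@dataclass
class FabricTensor:
    """MIL fabric tensor with descending eigen-decomposition.

    ``eigenvalues[0] >= eigenvalues[1] >= eigenvalues[2] > 0`` are the
    MIL ellipsoid semi-axis lengths (in voxels, up to a constant factor)
    and ``eigenvectors[:, i]`` the matching orthonormal directions.  The
    mean trabecular direction is the first eigenvector.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def mtd(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


@dataclass
class RigidTransform:
    """Rotation about a pivot (physical μm coordinates) plus translation."""

    rotation: np.ndarray
    translation: np.ndarray
    pivot: np.ndarray

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise GeometryError("rotation matrix must have determinant +1")

    def apply_point(self, p: np.ndarray) -> np.ndarray:
        return self.rotation @ (np.asarray(p, float) - self.pivot) + self.pivot + self.translation


def gaussian_kernel_1d(support: int, sigma: float) -> np.ndarray:
    """Discrete Gaussian on offsets -support..support, renormalised to unit sum."""
    if support < 1 or support % 2 == 0:
        raise ParameterError(f"support must be odd and >= 1, got {support}")
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    x = np.arange(-support, support + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def denoise(vol: ScalarVolume, support: int = 3, sigma: float = 1.2) -> ScalarVolume:
    """Truncated Gaussian filter (kernel half-width ``support``, width 2·support+1).

    Separable convolution with edge replication at the borders; the
    kernel is renormalised so constants are preserved exactly.
    """
    k = gaussian_kernel_1d(support, sigma)
    out = np.asarray(vol.data, dtype=np.float64)
    for axis in range(3):
        out = ndi.correlate1d(out, k, axis=axis, mode="nearest")
    return vol.copy_with(out.astype(np.float32))


def segment(vol: ScalarVolume, threshold_gsv: float = 39300.0) -> BinaryVolume:
    """Global threshold: a voxel is bone iff its intensity is >= threshold."""
    return BinaryVolume(data=vol.data >= threshold_gsv, voxel_size=vol.voxel_size)


def _fibonacci_hemisphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n quasi-uniform unit directions on a hemisphere, randomly rotated.

    Directions are orientation lines (u and -u equivalent), so a
    hemisphere suffices; a random seeded rotation removes alignment of
    the set with the grid axes.
    """
    i = np.arange(n, dtype=float) + 0.5
    z = i / n  # upper hemisphere
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # random rotation via QR of a Gaussian matrix
    q, rmat = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(rmat))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return dirs @ q.T


def _mil_one_direction(
    mask: np.ndarray,
    roi: np.ndarray | None,
    u: np.ndarray,
    line_spacing: float,
    step: float,
) -> tuple[float, int]:
    """Total bone length (voxels) and bone-run count along lines parallel to u."""
    shape = np.array(mask.shape, float)
    # orthonormal frame (u, v, w)
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    center = (shape - 1) / 2.0
    corners = np.array(
        [[x, y, z] for x in (0, shape[0] - 1) for y in (0, shape[1] - 1) for z in (0, shape[2] - 1)]
    ) - center
    half_diag = np.abs(corners @ u).max()
    ext_v = np.abs(corners @ v).max()
    ext_w = np.abs(corners @ w).max()
    sv = np.arange(-ext_v, ext_v + line_spacing, line_spacing, dtype=np.float32)
    sw = np.arange(-ext_w, ext_w + line_spacing, line_spacing, dtype=np.float32)
    t = np.arange(-half_diag, half_diag + step, step, dtype=np.float32)
    gv, gw = np.meshgrid(sv, sw, indexing="ij")
    origins = gv.ravel()[:, None] * v.astype(np.float32) + gw.ravel()[:, None] * w.astype(np.float32)
    n_lines, n_t = len(origins), len(t)
    # nearest-neighbour sampling via flat integer gather, one axis at a time
    dims = np.array(mask.shape, np.int32)
    inside = np.ones((n_lines, n_t), bool)
    flat = np.zeros((n_lines, n_t), np.intp)
    strides = np.array([mask.shape[1] * mask.shape[2], mask.shape[2], 1], np.intp)
    for ax in range(3):
        ci = np.rint(origins[:, ax : ax + 1] + t[None, :] * np.float32(u[ax]) + np.float32(center[ax]))
        inside &= (ci >= 0) & (ci <= dims[ax] - 1)
        flat += np.clip(ci, 0, dims[ax] - 1).astype(np.intp) * strides[ax]
    bone = mask.ravel()[flat.ravel()].reshape(n_lines, n_t) & inside
    valid = inside
    if roi is not None:
        in_roi = roi.ravel()[flat.ravel()].reshape(n_lines, n_t) & inside
        bone = bone & in_roi
        valid = in_roi
    total_bone = float(bone.sum()) * step
    # a bone run starts where a valid bone sample is not preceded by one
    prev_bone = np.zeros_like(bone)
    prev_bone[:, 1:] = bone[:, :-1] & valid[:, :-1]
    runs = int((bone & ~prev_bone).sum())
    return total_bone, runs


def central_roi(mask: BinaryVolume, fraction: float = 0.6) -> BinaryVolume:
    """Central ball ROI for fabric estimation, excluding the cortical shell.

    A ball around the bone centroid with radius ``fraction`` of the
    centroid-to-farthest-bone distance is dominated by trabecular
    structure, so the dense shell does not bias the fabric tensor.
    """
    idx = np.argwhere(mask.data)
    if len(idx) == 0:
        raise DegenerateStructureError("empty mask; cannot build a central ROI")
    c = idx.mean(axis=0)
    rmax = np.sqrt(((idx - c) ** 2).sum(axis=1)).max()
    r = fraction * rmax
    shape = mask.shape
    xi = (np.arange(shape[0], dtype=np.float32) - c[0])[:, None, None] ** 2
    yi = (np.arange(shape[1], dtype=np.float32) - c[1])[None, :, None] ** 2
    zi = (np.arange(shape[2], dtype=np.float32) - c[2])[None, None, :] ** 2
    return mask.copy_with(xi + yi + zi <= r * r)


def structure_tensor_axis(
    mask: np.ndarray, roi: np.ndarray | None = None, sigma: float = 2.0
) -> np.ndarray:
    """Dominant structure axis from the gradient structure tensor.

    Gradients of the smoothed occupancy field are perpendicular to
    rod-like structures, so the eigenvector of the smallest eigenvalue
    of Σ ∇I∇Iᵀ over the ROI is the structure axis.  Resolves the axis
    to a fraction of a degree, well below the angular resolution of
    intercept counting along a finite direction set.
    """
    f = ndi.gaussian_filter(mask.astype(np.float32), sigma)
    g = np.gradient(f)
    w = roi if roi is not None else np.ones(mask.shape, bool)
    st = np.array([[(g[i] * g[j])[w].sum() for j in range(3)] for i in range(3)])
    mu, vecs = np.linalg.eigh(st)
    return vecs[:, 0]


def estimate_fabric(
    mask: BinaryVolume,
    roi: BinaryVolume | None = None,
    n_directions: int = 128,
    seed: int = 0,
    line_spacing: float = 3.0,
    step: float = 1.0,
    refine: bool = True,
) -> FabricTensor:
    """Mean-intercept-length fabric tensor by directed line probing.

    Test lines at ``line_spacing`` voxels cover the volume along
    ``n_directions`` quasi-uniform orientations (Fibonacci hemisphere,
    seeded random rotation); MIL(u) = bone length / bone-run count.  The
    MIL ellipsoid ``u'Mu = MIL(u)^-2`` is fitted by linear least squares
    and eigen-decomposed; eigenvalues are the ellipsoid semi-axes sorted
    descending, so the first eigenvector is the mean trabecular direction.
    """
    m = mask.data
    r = roi.data if roi is not None else None
    if r is not None:
        ii = np.argwhere(r)
        lo = ii.min(axis=0)
        hi = ii.max(axis=0) + 1
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        m = np.ascontiguousarray(m[sl])
        r = np.ascontiguousarray(r[sl])
    region = m if r is None else (m & r)
    n_bone = int(region.sum())
    n_total = int(m.size if r is None else r.sum())
    if n_bone == 0 or n_bone == n_total:
        raise DegenerateStructureError("ROI must contain both bone and background")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_hemisphere(n_directions, rng)
    mil = np.empty(len(dirs))
    for i, u in enumerate(dirs):
        total, runs = _mil_one_direction(m, r, u, line_spacing, step)
        mil[i] = total / max(runs, 1)
    if np.any(mil <= 0):
        raise DegenerateStructureError("no bone intercepts along some directions")
    # fit symmetric M with u'Mu = 1/MIL^2
    u = dirs
    design = np.column_stack(
        [u[:, 0] ** 2, u[:, 1] ** 2, u[:, 2] ** 2,
         2 * u[:, 0] * u[:, 1], 2 * u[:, 0] * u[:, 2], 2 * u[:, 1] * u[:, 2]]
    )
    rhs = 1.0 / mil**2
    c, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    M = np.array([[c[0], c[3], c[4]], [c[3], c[1], c[5]], [c[4], c[5], c[2]]])
    mu, vecs = np.linalg.eigh(M)
    if np.any(mu <= 0):
        raise DegenerateStructureError("MIL ellipsoid fit is not positive definite")
    lam = 1.0 / np.sqrt(mu)  # semi-axes; eigh ascending in mu => lam descending
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vecs = vecs[:, order]
    if refine and lam[0] / lam[1] > 1.02:
        # sharpen the principal direction below the MIL angular resolution;
        # accept only if it corroborates the MIL axis (rod-like structure)
        e1_new = structure_tensor_axis(m, r)
        if abs(float(e1_new @ vecs[:, 0])) > np.cos(np.radians(15.0)):
            if e1_new @ vecs[:, 0] < 0:
                e1_new = -e1_new
            Rfix = _rotation_between(vecs[:, 0], e1_new)
            vecs = Rfix @ vecs
    # deterministic sign: principal axes point into the upper half-space
    for j in range(3):
        kmax = np.argmax(np.abs(vecs[:, j]))
        if vecs[kmax, j] < 0:
            vecs[:, j] *= -1
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1
    return FabricTensor(tensor=M, eigenvalues=lam, eigenvectors=vecs)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def apply_transform(
    vol: ScalarVolume | BinaryVolume, transform: RigidTransform, order: int = 1
) -> ScalarVolume | BinaryVolume:
    """Resample a volume under a rigid transform (output grid = input grid).

    Grey-scale volumes are interpolated linearly (``order=1``); binary
    masks should be resampled with ``order=0`` (nearest neighbour).
    """
    vs = vol.voxel_size
    R = transform.rotation
    pivot_vox = transform.pivot / vs
    shift_vox = transform.translation / vs
    # output voxel q maps to input voxel R^-1 (q - shift - pivot) + pivot
    Rinv = R.T
    offset = pivot_vox - Rinv @ (pivot_vox + shift_vox)
    data = vol.data
    is_binary = data.dtype == bool
    arr = data.astype(np.float32) if (is_binary or order > 0) else data
    out = ndi.affine_transform(
        arr, Rinv, offset=offset, order=order, mode="constant", cval=0.0
    )
    if is_binary:
        return vol.copy_with(out > 0.5)
    return vol.copy_with(out)


def align(
    vol: ScalarVolume,
    fabric: FabricTensor,
    fovea_direction: np.ndarray | None = None,
    skip_below_rad: float = 0.0,
) -> tuple[ScalarVolume, RigidTransform]:
    """Rotate the volume so the MTD is parallel to the supero-inferior axis.

    The minimal rotation taking the principal fabric eigenvector onto +z
    is applied about the volume centre.  If a fovea direction is given
    (unit vector in the un-aligned frame), a second rotation about z
    brings it perpendicular to the antero-posterior (+y) axis, pointing
    medially (-x).

    If the total rotation angle is below ``skip_below_rad`` the volume
    is returned untouched with an identity transform: below the grid's
    angular resolution (about one voxel at the head radius) resampling
    cannot improve the alignment but does degrade thin structures.
    """
    e1 = fabric.mtd.copy()
    if e1[2] < 0:
        e1 = -e1
    R1 = _rotation_between(e1, np.array([0.0, 0.0, 1.0]))
    R = R1
    if fovea_direction is not None:
        f = np.asarray(fovea_direction, float)
        f = f / np.linalg.norm(f)
        if np.linalg.norm(np.cross(f, e1)) < 1e-3:
            raise GeometryError("fovea direction is parallel to the MTD")
        fp = R1 @ f
        # rotate about z so the transverse component of f points to -x (medial)
        ang = np.arctan2(fp[1], fp[0]) - np.pi
        ca, sa = np.cos(-ang), np.sin(-ang)
        Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        R = Rz @ R1
    center = (np.array(vol.shape, float) - 1) / 2.0 * vol.voxel_size
    angle = np.arccos(np.clip((np.trace(R) - 1) / 2.0, -1.0, 1.0))
    if angle < skip_below_rad:
        logger.info(
            "alignment rotation %.3f deg below grid resolution; volume left untouched",
            np.degrees(angle),
        )
        transform = RigidTransform(rotation=np.eye(3), translation=np.zeros(3), pivot=center)
        return vol, transform
    transform = RigidTransform(rotation=R, translation=np.zeros(3), pivot=center)
    out = apply_transform(vol, transform, order=1)
    return out, transform
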