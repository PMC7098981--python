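"""Volume containers and file I/O.

Conventions used throughout the package:

* Arrays are indexed ``data[x, y, z]`` with ``z`` the axial slice index.
  Anatomically, +x = lateral, +y = anterior, +z = superior; "proximal"
  slices are the highest z indices.
* Voxel size is isotropic, in micrometres.  Physical coordinates are
  voxel-centre positions, ``p = index * voxel_size`` (0-based indices).
* Intensities are 16-bit unsigned grey-scale values (GSV, 0..65535), the
  scale on which the global bone threshold is defined.  Signed integer
  inputs are shifted into this range with a logged warning.

Supported formats: TIFF stacks (multi-page file or a directory of
single-slice files), MetaImage (.mha/.mhd) and NIfTI (.nii/.nii.gz).
TIFF carries no trustworthy physical metadata, so a voxel size must be
supplied for it; MetaImage/NIfTI spacings are interpreted as millimetres
(their conventional unit) and converted to μm.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

logger = logging.getLogger(__name__)

__all__ = [
    "ScalarVolume",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "write_labelmap",
    "read_labelmap",
]


@dataclass
class ScalarVolume:
    """3D grey-scale image with isotropic voxel size in μm."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"expected a 3D volume, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise MetadataError(f"voxel size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def physical_size_mm(self) -> tuple[float, float, float]:
        """Physical extent (mm) along each axis: n_voxels × voxel size."""
        return tuple(n * self.voxel_size / 1000.0 for n in self.data.shape)

    def copy_with(self, data: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(data=data, voxel_size=self.voxel_size)


@dataclass
class BinaryVolume:
    """Boolean bone/background grid sharing geometry with its source volume."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D mask, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise MetadataError(f"voxel size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * (self.voxel_size / 1000.0) ** 3

    def copy_with(self, data: np.ndarray) -> "BinaryVolume":
        return BinaryVolume(data=np.asarray(data, bool), voxel_size=self.voxel_size)


def _shift_signed(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() < 0:
        offset = 1 << (arr.dtype.itemsize * 8 - 1)
        logger.warning(
            "signed input intensities shifted by +%d onto the unsigned GSV scale", offset
        )
        return arr.astype(np.int64) + offset
    return arr


def _read_tiff(path: Path) -> np.ndarray:
    import tifffile

    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FormatError(f"no TIFF slices found in directory {path}")
        arr = np.stack([tifffile.imread(str(p)) for p in slices], axis=0)
    else:
        arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr  # (z, y, x)


def read_volume(path, voxel_size_um: float | None = None) -> ScalarVolume:
    """Read a 3D volume, normalising axis order to (x, y, z).

    ``voxel_size_um`` overrides (or supplies, for TIFF) the file's voxel
    size.  File spacings from MetaImage/NIfTI headers are taken as mm.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    vs = None
    try:
        if path.is_dir() or suffixes.endswith((".tif", ".tiff")):
            arr = _read_tiff(path)
        elif suffixes.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            arr = sitk.GetArrayFromImage(img)  # (z, y, x)
            sp = img.GetSpacing()
            vs = float(sp[0]) * 1000.0
        elif suffixes.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj)  # nibabel is (x, y, z)
            arr = np.transpose(arr, (2, 1, 0))  # unify to (z, y, x) for the common path
            vs = float(img.header.get_zooms()[0]) * 1000.0
        else:
            raise FormatError(f"unsupported volume format: {path.name}")
    except FormatError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"could not read {path}: {exc}") from exc

    if voxel_size_um is not None:
        vs = float(voxel_size_um)
    if vs is None or not vs > 0:
        raise MetadataError(
            f"{path.name} carries no voxel size; pass voxel_size_um explicitly"
        )
    arr = _shift_signed(np.asarray(arr))
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))  # (x, y, z)
    return ScalarVolume(data=data, voxel_size=vs)


def write_volume(vol: ScalarVolume | BinaryVolume, path) -> None:
    """Write a volume; format chosen from the file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    zyx = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), zyx)
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(zyx)
        img.SetSpacing([vol.voxel_size / 1000.0] * 3)
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([vol.voxel_size / 1000.0] * 3 + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))
    else:
        raise FormatError(f"unsupported output format: {path.name}")


def write_labelmap(labels, path) -> None:
    """Write a region label map as an integer volume plus a CSV sidecar.

    The sidecar ``<path>.labels.csv`` lists one row per named VOI
    (macro and sub-regions) with its member label integers.
    """
    path = Path(path)
    vol = ScalarVolume(
        data=labels.labels.astype(np.uint16), voxel_size=labels.voxel_size
    )
    write_volume(vol, path)
    sidecar = path.parent / (path.name + ".labels.csv")
    table = labels.table.copy()
    table["labels"] = table["labels"].map(lambda ls: ";".join(str(l) for l in ls))
    table.to_csv(sidecar, index=False, quoting=csv.QUOTE_MINIMAL)


def read_labelmap(path, voxel_size_um: float | None = None):
    """Read back a label map written by :func:`write_labelmap`."""
    from .head_geometry import RegionLabelMap

    path = Path(path)
    vol = read_volume(path, voxel_size_um=voxel_size_um)
    sidecar = path.parent / (path.name + ".labels.csv")
    table = pd.read_csv(sidecar)
    if len(table):
        table["labels"] = table["labels"].map(
            lambda s: tuple(int(x) for x in str(s).split(";"))
        )
    return RegionLabelMap(
        labels=vol.data.astype(np.int32), table=table, voxel_size=vol.voxel_size
    )
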