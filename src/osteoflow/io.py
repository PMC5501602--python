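"""Volume and field I/O.

Volumes travel as MetaImage (.mha / .mhd) or NIfTI (.nii / .nii.gz) via
SimpleITK, with the in-memory convention data[ix, iy, iz] and voxel size in
meters (stored as millimeters in the file headers, the medical-imaging
convention).  Axisymmetric simulation fields can be dumped as legacy ASCII
VTK structured points for inspection.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .uct_pipeline import BinaryMask, VoxelVolume

__all__ = ["read_volume", "write_volume", "write_mask", "read_mask",
           "write_field_vtk", "sha256_of"]

_SUPPORTED = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED):
        raise ValueError(f"unsupported volume format: {path.name!r} "
                         f"(supported: {', '.join(_SUPPORTED)})")


def write_volume(vol: VoxelVolume | BinaryMask, path: str | Path) -> Path:
    """Write a volume or mask losslessly (array dtype, spacing, origin)."""
    path = Path(path)
    _check_path(path)
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    mm = vol.voxel_size * 1e3
    img.SetSpacing((mm, mm, mm))
    img.SetOrigin(tuple(float(o) * 1e3 for o in vol.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    return write_volume(mask, path)


def read_volume(path: str | Path, week: int | None = None) -> VoxelVolume:
    path = Path(path)
    _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0], rtol=1e-9):
        raise ValueError(f"anisotropic voxels not supported: {spacing}")
    origin = tuple(o * 1e-3 for o in img.GetOrigin())
    return VoxelVolume(data.astype(float), spacing[0] * 1e-3, origin, week=week)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.voxel_size, vol.origin)


def write_field_vtk(field2d: np.ndarray, dr: float, dz: float, path: str | Path,
                    name: str = "field") -> Path:
    """Dump an (nr, nz) cell-centered axisymmetric field as legacy ASCII VTK
    structured points (x = r, y = z)."""
    path = Path(path)
    nr, nz = field2d.shape
    lines = [
        "# vtk DataFile Version 3.0",
        f"osteoflow axisymmetric {name}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nr} {nz} 1",
        f"ORIGIN {0.5 * dr:.9e} {0.5 * dz:.9e} 0.0",
        f"SPACING {dr:.9e} {dz:.9e} 1.0",
        f"POINT_DATA {nr * nz}",
        f"SCALARS {name} double 1",
        "LOOKUP_TABLE default",
    ]
    vals = field2d.T.ravel()  # x fastest
    lines.extend(f"{v:.9e}" for v in vals)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
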