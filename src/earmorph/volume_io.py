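"""Reading, writing and resampling of 3D masks and grayscale volumes.

Arrays are stored in (Z, Y, X) index order while physical voxel spacing is
kept as ``(sx, sy, sz)`` in millimetres, matching the radiological convention
of quoting in-plane (XY) resolution first.  All physical quantities downstream
are computed from the spacing, never from voxel counts alone, because the
clinical grids of interest are anisotropic (e.g. 0.45 x 0.45 mm in-plane,
0.40 mm out-of-plane).

Supported formats: NIfTI (``.nii``/``.nii.gz``) via nibabel, MetaImage
(``.mha``/``.mhd``) via SimpleITK, and numbered TIFF/PNG slice stacks with a
mandatory JSON spacing sidecar.  A file without usable spacing metadata is an
error -- never a silent 1 mm default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "GrayscaleVolume",
    "read_volume",
    "write_volume",
    "resample",
    "resample_isotropic",
    "upscale_xz",
]


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(sp)}")
    if not all(np.isfinite(s) and s > 0 for s in sp):
        raise ValueError(f"spacing components must be positive and finite, got {sp}")
    return sp  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """A 3D binary segmentation mask with physical voxel spacing.

    Parameters
    ----------
    data
        Boolean array in (Z, Y, X) order.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm; all components > 0.
    origin
        Physical offset of voxel (0, 0, 0) in mm, ``(x, y, z)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask data must contain only {0, 1}")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.spacing
        return (sz, sy, sx)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) of the array in mm."""
        nz, ny, nx = self.data.shape
        sx, sy, sz = self.spacing
        return (nx * sx, ny * sy, nz * sz)

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        sx, sy, sz = self.spacing
        return abs(sy - sx) <= rtol * sx and abs(sz - sx) <= rtol * sx


@dataclass
class GrayscaleVolume:
    """A 3D scalar field (e.g. linear attenuation in 1/cm) with spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("volume contains non-finite values")
        self.data = arr
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.spacing
        return (sz, sy, sx)


Volume = Union[VoxelGrid, GrayscaleVolume]

_STACK_SUFFIXES = {".tif", ".tiff", ".png"}


def _wrap(data: np.ndarray, spacing, origin) -> Volume:
    """Binary content becomes a VoxelGrid, anything else a GrayscaleVolume."""
    vals = np.unique(data)
    if len(vals) <= 2 and np.isin(vals, (0, 1)).all():
        return VoxelGrid(data.astype(bool), spacing, origin)
    return GrayscaleVolume(data, spacing, origin)


def read_volume(path: str | Path) -> Volume:
    """Read a volume from NIfTI, MetaImage, or a TIFF/PNG slice stack.

    Stack import expects ``path`` to be a directory of numbered slices plus a
    sidecar ``spacing.json`` containing ``{"spacing_mm": [sx, sy, sz]}``.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        Unreadable format, or absent/zero spacing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    if path.is_dir():
        return _read_stack(path)
    suffixes = "".join(path.suffixes[-2:])
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        try:
            spacing = _check_spacing(zooms)
        except ValueError as e:
            raise ValueError(f"spacing unknown or invalid in {path}: {e}") from e
        data = np.asanyarray(img.dataobj)  # (X, Y, Z)
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return _wrap(np.ascontiguousarray(data.T), spacing, origin)
    if path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        try:
            spacing = _check_spacing(img.GetSpacing())
        except ValueError as e:
            raise ValueError(f"spacing unknown or invalid in {path}: {e}") from e
        data = sitk.GetArrayFromImage(img)  # already (Z, Y, X)
        return _wrap(data, spacing, tuple(img.GetOrigin()))
    raise ValueError(f"unsupported volume format: {path.name}")


def _read_stack(dirpath: Path) -> Volume:
    sidecar = dirpath / "spacing.json"
    if not sidecar.exists():
        raise ValueError(
            f"spacing unknown: slice-stack import requires {sidecar} "
            '({"spacing_mm": [sx, sy, sz]})'
        )
    meta = json.loads(sidecar.read_text())
    if "spacing_mm" not in meta:
        raise ValueError(f"spacing unknown: no 'spacing_mm' key in {sidecar}")
    spacing = _check_spacing(meta["spacing_mm"])
    files = sorted(p for p in dirpath.iterdir() if p.suffix.lower() in _STACK_SUFFIXES)
    if not files:
        raise ValueError(f"no TIFF/PNG slices found in {dirpath}")
    import imageio.v3 as iio

    slices = [np.asarray(iio.imread(f)) for f in files]
    data = np.stack(slices, axis=0)  # slices along Z
    return _wrap(data, spacing, meta.get("origin_mm", (0.0, 0.0, 0.0)))


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a grid or grayscale volume to NIfTI or MetaImage."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, VoxelGrid):
        data = vol.data.astype(np.uint8)
    else:
        data = np.asarray(vol.data, dtype=np.float32)
    suffixes = "".join(path.suffixes[-2:])
    if suffixes.endswith((".nii", ".nii.gz")):
        sx, sy, sz = vol.spacing
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
        img.header.set_zooms((sx, sy, sz))
        nib.save(img, str(path))
        return path
    if path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(data)
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
        return path
    raise ValueError(f"unsupported volume format: {path.name}")


def resample(
    grid: VoxelGrid,
    target_spacing: Sequence[float],
    interpolation: str = "linear",
) -> VoxelGrid:
    """Resample a binary mask to a new voxel spacing.

    ``interpolation="linear"`` interpolates the 0/1 indicator field and
    thresholds at 0.5 (the default; boundary behaviour mimics contouring on
    upscaled slices); ``"nearest"`` uses nearest-neighbour lookup.  The
    physical extent is preserved to within one voxel per axis.
    """
    target = _check_spacing(target_spacing)
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    ext_x, ext_y, ext_z = grid.extent_mm
    for ext, t, name in ((ext_x, target[0], "x"), (ext_y, target[1], "y"), (ext_z, target[2], "z")):
        if t >= ext:
            raise ValueError(
                f"target spacing {t} mm >= physical extent {ext} mm along {name}: "
                "would yield fewer than 2 voxels"
            )
    if target == grid.spacing:
        return VoxelGrid(grid.data.copy(), grid.spacing, grid.origin)
    old_zyx = grid.spacing_zyx
    new_zyx = (target[2], target[1], target[0])
    new_shape = tuple(
        max(int(round(n * o / t)), 1) for n, o, t in zip(grid.data.shape, old_zyx, new_zyx)
    )
    zoom = tuple(ns / n for ns, n in zip(new_shape, grid.data.shape))
    order = 1 if interpolation == "linear" else 0
    out = ndimage.zoom(
        grid.data.astype(np.float32), zoom, order=order, mode="grid-constant",
        cval=0.0, grid_mode=True,
    )
    mask = out >= 0.5 if order == 1 else out > 0.5
    return VoxelGrid(mask, target, grid.origin)


def resample_isotropic(grid: VoxelGrid, target: float | None = None) -> VoxelGrid:
    """Resample to an isotropic grid; default target is ``min(spacing)``."""
    if target is None:
        target = min(grid.spacing)
    if grid.is_isotropic() and abs(grid.spacing[0] - target) <= 1e-9:
        return grid
    return resample(grid, (target, target, target))


def upscale_xz(grid: VoxelGrid, factor: int = 5) -> VoxelGrid:
    """Upscale in the X and Z directions (contouring convenience preset).

    A 10x10x10 grid at (0.45, 0.45, 0.40) becomes 50 x 10 x 50 voxels at
    spacing (0.09, 0.45, 0.08).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    sx, sy, sz = grid.spacing
    return resample(grid, (sx / factor, sy, sz / factor))
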