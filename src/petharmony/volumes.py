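"""Axis-aligned PET volumes, region masks, NIfTI I/O, regridding and erosion.

Grids are axis-aligned in world (mm) coordinates with no orientation
matrix: the world position of voxel index ``i`` along an axis is
``origin + i * spacing``, where ``origin`` is the *center* of voxel 0.
This is sufficient for simulated phantoms and for patient volumes whose
affine is diagonal; oblique acquisitions are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "VoxelGrid",
    "RegionMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "regrid",
    "regrid_geometry",
    "erode_mask",
]

ValueKind = Literal["concentration", "suv"]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of an axis-aligned voxel grid."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def fov_mm(self) -> np.ndarray:
        """Physical extent (edge to edge) per axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing_mm)

    @property
    def edge_origin_mm(self) -> np.ndarray:
        """World coordinate of the outer corner of voxel (0, 0, 0)."""
        return np.asarray(self.origin_mm) - np.asarray(self.spacing_mm) / 2.0

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


def _as3(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise ValueError(f"expected scalar or 3-vector, got {v!r}")
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class VoxelGrid:
    """3-D scalar volume carrying activity concentration (kBq/mL) or SUV."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_kind: ValueKind = "suv"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")
        self.spacing_mm = _as3(self.spacing_mm)
        self.origin_mm = _as3(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.values.shape, self.spacing_mm, self.origin_mm)

    @property
    def voxel_volume_ml(self) -> float:
        return self.geometry.voxel_volume_ml

    def total_activity(self) -> float:
        """Volume integral of the values (value * mm^3)."""
        return float(self.values.sum()) * float(np.prod(self.spacing_mm))


@dataclass
class RegionMask:
    """Binary region aligned to a voxel grid, labeled by anatomical role."""

    role: str  # "liver", "blood_pool" or "lesion"
    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    index: int | None = None  # distinguishes lesion_1, lesion_2, ...

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("RegionMask values must be a 3-D array")
        self.spacing_mm = _as3(self.spacing_mm)
        self.origin_mm = _as3(self.origin_mm)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.values.shape, self.spacing_mm, self.origin_mm)

    @property
    def label(self) -> str:
        if self.role == "lesion" and self.index is not None:
            return f"lesion_{self.index}"
        return self.role

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def aligned_with(self, other: "VoxelGrid | RegionMask", atol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _parse_affine(aff: np.ndarray, path) -> tuple[tuple, tuple]:
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-4):
        raise ValueError(
            f"{path}: affine (srow/qform) is not axis-aligned diagonal; "
            "oblique volumes are not supported"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine pixdim entries must be positive, got {spacing}")
    return _as3(spacing), _as3(aff[:3, 3])


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a volume as NIfTI-1 (float32 data, diagonal affine)."""
    img = nib.Nifti1Image(grid.values.astype(np.float32), _affine(grid.spacing_mm, grid.origin_mm))
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = grid.value_kind.encode()[:79]
    nib.save(img, str(path))


def read_volume(path, value_kind: ValueKind | None = None) -> VoxelGrid:
    """Read a NIfTI-1 volume; metadata round-trips exactly, data as float32."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed header
        raise ValueError(f"{path}: could not parse NIfTI header: {exc}") from exc
    spacing, origin = _parse_affine(img.affine, path)
    if value_kind is None:
        descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(errors="ignore")
        value_kind = "concentration" if descrip == "concentration" else "suv"
    return VoxelGrid(np.asanyarray(img.dataobj), spacing, origin, value_kind)


def write_mask(mask: RegionMask, path) -> None:
    """Write a binary mask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm)
    )
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_mask(path, role: str, index: int | None = None) -> RegionMask:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: could not parse NIfTI header: {exc}") from exc
    spacing, origin = _parse_affine(img.affine, path)
    return RegionMask(role, np.asanyarray(img.dataobj) > 0, spacing, origin, index=index)


# ---------------------------------------------------------------------------
# Regridding


def regrid_geometry(
    source: GridGeometry,
    pixel_mm: float,
    slice_mm: float | None = None,
    matrix: tuple[int, int] | None = None,
) -> GridGeometry:
    """Target geometry with a new pixel size covering the source field of view.

    The physical field of view is preserved: the outer edges of the source
    grid are kept and the new voxel centers are placed half a voxel inside,
    so e.g. 192 pixels at 3.64 mm map onto 256 pixels at 2.73 mm over the
    identical 698.9 mm extent.
    """
    slice_mm = source.spacing_mm[2] if slice_mm is None else slice_mm
    new_spacing = (float(pixel_mm), float(pixel_mm), float(slice_mm))
    fov = source.fov_mm
    if matrix is not None:
        shape = (int(matrix[0]), int(matrix[1]), source.shape[2])
    else:
        shape = tuple(int(round(fov[ax] / new_spacing[ax])) for ax in range(3))
    edge = source.edge_origin_mm
    # center the new grid on the source FOV
    new_fov = np.asarray(shape) * np.asarray(new_spacing)
    shift = (fov - new_fov) / 2.0
    origin = tuple(edge + shift + np.asarray(new_spacing) / 2.0)
    return GridGeometry(shape, new_spacing, origin)


def _check_overlap(source: GridGeometry, target: GridGeometry) -> None:
    s0, t0 = source.edge_origin_mm, target.edge_origin_mm
    s1, t1 = s0 + source.fov_mm, t0 + target.fov_mm
    if np.any(t1 <= s0) or np.any(t0 >= s1):
        raise ValueError(
            f"target grid (extent {t0}..{t1} mm) does not overlap source ({s0}..{s1} mm)"
        )


def regrid(
    volume: VoxelGrid | RegionMask,
    target: GridGeometry,
    interpolation: Literal["linear", "nearest"] | None = None,
) -> VoxelGrid | RegionMask:
    """Resample a volume or mask onto a target grid geometry.

    Masks always use nearest-neighbor interpolation; volumes default to
    linear. Sampling outside the source extent clamps to the edge value,
    which keeps constant volumes constant.
    """
    is_mask = isinstance(volume, RegionMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    if is_mask and interpolation != "nearest":
        raise ValueError("masks must be regridded with nearest interpolation")
    src = volume.geometry
    _check_overlap(src, target)
    if src == target:
        return replace(volume, values=volume.values.copy())

    coords = np.meshgrid(
        *[
            (target.voxel_centers(ax) - src.origin_mm[ax]) / src.spacing_mm[ax]
            for ax in range(3)
        ],
        indexing="ij",
    )
    order = 0 if interpolation == "nearest" else 1
    data = volume.values.astype(np.float64) if is_mask else volume.values
    out = ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    if is_mask:
        return RegionMask(volume.role, out > 0.5, target.spacing_mm, target.origin_mm,
                          index=volume.index)
    return VoxelGrid(out, target.spacing_mm, target.origin_mm, volume.value_kind)


# ---------------------------------------------------------------------------
# Erosion


def erode_mask(
    mask: RegionMask, voxels_per_axis: int = 3
) -> tuple[RegionMask, tuple[float, float, float]]:
    """Box-erode a mask by ``voxels_per_axis`` voxels in every direction.

    A voxel survives iff its full (2k+1)^3 box neighborhood lies inside the
    mask (the volume border counts as outside). Returns the eroded mask and
    the kernel's physical reach per axis, k * spacing, rounded to 0.1 mm —
    8.2 x 8.2 x 8.4 mm for k = 3 on a 2.73/2.73/2.79 mm grid.
    """
    k = int(voxels_per_axis)
    if k < 0:
        raise ValueError("voxels_per_axis must be >= 0")
    extent = tuple(round(k * s, 1) for s in mask.spacing_mm)
    if k == 0:
        return replace(mask, values=mask.values.copy()), extent
    structure = np.ones((2 * k + 1,) * 3, dtype=bool)
    eroded = ndimage.binary_erosion(mask.values, structure=structure, border_value=0)
    if not eroded.any():
        warnings.warn(
            f"erosion by {k} voxels emptied mask '{mask.label}'", stacklevel=2
        )
    return replace(mask, values=eroded), extent
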