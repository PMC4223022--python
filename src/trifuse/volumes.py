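"""Scalar volumes, binary masks, grids and intensity windowing.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` in a fixed right-handed world frame.
* Voxel *centers*: the world coordinate of voxel index ``i`` is
  ``origin + i * spacing`` (mm), 0-based indices.
* All geometry is carried in millimetres; volumes are reported in cm^3.

CT intensities are Hounsfield units, MR arbitrary units, PET activity/SUV.
Before fusion every modality is mapped onto a common [0, 1] display scale by
:func:`window_normalize`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import (
    DimensionalityError,
    GeometryError,
    ParameterError,
    TransformError,
)

__all__ = [
    "GridSpec",
    "ImageVolume",
    "GTVMask",
    "RigidTransform",
    "WindowSpec",
    "DEFAULT_WINDOWS",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_transform",
    "resample_to_grid",
    "window_normalize",
    "percentile_window",
    "mask_volume_cm3",
]


@dataclass(frozen=True)
class GridSpec:
    """A finite axis-aligned voxel grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise DimensionalityError("GridSpec is strictly three-dimensional")
        if any(s <= 0 for s in self.shape):
            raise ParameterError("grid shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("voxel spacing must be strictly positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the first/last voxel centers."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def same_as(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _require_same_grid(a: GridSpec, b: GridSpec, what: str = "volumes") -> None:
    if not a.same_as(b):
        raise GeometryError(f"{what} are not on the same grid: {a} vs {b}")


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel-center geometry.

    ``data`` is indexed ``(x, y, z)``; ``spacing``/``origin`` are in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("voxel spacing must be strictly positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.spacing, self.origin)

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)


@dataclass
class GTVMask:
    """A binary delineation (gross tumor volume) on a grid."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionalityError("mask must be 3D")
        if arr.dtype != bool:
            values = np.unique(arr)
            if not np.all(np.isin(values, (0, 1))):
                raise ParameterError("mask values must be 0/1")
            arr = arr.astype(bool)
        if tuple(arr.shape) != self.grid.shape:
            raise GeometryError(
                f"mask shape {arr.shape} does not match grid shape {self.grid.shape}"
            )
        self.data = arr

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body map ``w_ref = R @ w_mov + t`` between world frames (mm).

    ``rotation`` must be orthonormal with determinant +1 (tolerance 1e-6).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(-1)
        if R.shape != (3, 3) or t.shape != (3,):
            raise TransformError("rigid transform needs a 3x3 rotation and length-3 translation")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise TransformError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise TransformError("rotation determinant must be +1 (no reflections)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise TransformError("expected a 4x4 homogeneous matrix")
        if not np.allclose(M[3], (0, 0, 0, 1), atol=1e-9):
            raise TransformError("last row of a rigid 4x4 matrix must be [0 0 0 1]")
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class WindowSpec:
    """Display window: maps ``[level - width/2, level + width/2]`` onto [0, 1]."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")


#: Conventional windows (modality units). ``ct_bone`` is the default CT window
#: for fusion display; ``unit`` is the identity window on already-normalized data.
DEFAULT_WINDOWS: dict[str, WindowSpec] = {
    "ct_bone": WindowSpec(level=600.0, width=2800.0),
    "ct_brain": WindowSpec(level=40.0, width=80.0),
    "unit": WindowSpec(level=0.5, width=1.0),
}


# ---------------------------------------------------------------------------
# I/O (NIfTI-1/2 and NRRD through SimpleITK; masks stored as uint8)
# ---------------------------------------------------------------------------

def _volume_from_sitk(img: sitk.Image) -> ImageVolume:
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"expected a 3D image, file has {img.GetDimension()} dimensions"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-3):
        raise GeometryError(
            "image axes are not aligned with the world axes; resample the input "
            "onto an axis-aligned grid first (co-registered inputs are assumed)"
        )
    data = sitk.GetArrayFromImage(img).T  # sitk arrays are (z, y, x)
    return ImageVolume(data=data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def _volume_to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    return img


def load_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3D scalar volume from NIfTI-1/NIfTI-2 or NRRD.

    Intensities are returned unmodified in the file's native units.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # unreadable / unsupported format
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return _volume_from_sitk(img)


def save_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    sitk.WriteImage(_volume_to_sitk(vol), os.fspath(path))


def load_mask(path: str | os.PathLike, grid: GridSpec | None = None) -> GTVMask:
    """Read a binary mask (uint8 NIfTI/NRRD); optionally check it sits on ``grid``."""
    vol = load_volume(path)
    mask = GTVMask(data=vol.data, grid=vol.grid)
    if grid is not None:
        _require_same_grid(mask.grid, grid, "mask and reference grid")
    return mask


def save_mask(mask: GTVMask, path: str | os.PathLike) -> None:
    vol = ImageVolume(
        data=mask.data.astype(np.uint8),
        spacing=mask.grid.spacing,
        origin=mask.grid.origin,
    )
    save_volume(vol, path)


def load_transform(path: str | os.PathLike) -> RigidTransform:
    """Read a rigid transform from a 4x4 row-major plain-text matrix file."""
    M = np.loadtxt(os.fspath(path))
    return RigidTransform.from_matrix(M)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

#: Out-of-field fill values by modality: neutral background.
BACKGROUND_FILL = {"ct": -1000.0, "mr": 0.0, "pet": 0.0, "mask": 0.0}


def resample_to_grid(
    moving: ImageVolume,
    reference: GridSpec,
    transform: RigidTransform | None = None,
    interpolation: str = "trilinear",
    fill: float = 0.0,
) -> ImageVolume:
    """Resample ``moving`` onto ``reference`` under a rigid world-to-world map.

    ``transform`` maps moving-frame world coordinates into the reference frame
    (the output of a registration); identity by default.  ``interpolation`` is
    ``"trilinear"`` or ``"nearest"`` — nearest is mandatory for masks.
    Voxels that fall outside the moving field of view are set to ``fill``
    (use :data:`BACKGROUND_FILL`: CT -1000 HU, MR/PET 0).
    """
    from scipy import ndimage

    if transform is None:
        transform = RigidTransform.identity()
    if interpolation not in ("trilinear", "nearest"):
        raise ParameterError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0

    # output index j -> world -> moving world -> moving index i:
    #   i = S_m^-1 (R^T (S_r j + o_r - t) - o_m)
    S_m = np.asarray(moving.spacing)
    S_r = np.asarray(reference.spacing)
    R = transform.rotation
    matrix = (R.T * S_r[None, :]) / S_m[:, None]
    offset = (
        R.T @ (np.asarray(reference.origin) - transform.translation)
        - np.asarray(moving.origin)
    ) / S_m

    out = ndimage.affine_transform(
        moving.data.astype(float),
        matrix,
        offset=offset,
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=float(fill),
    )
    return ImageVolume(data=out, spacing=reference.spacing, origin=reference.origin)


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def window_normalize(vol: ImageVolume, window: WindowSpec) -> ImageVolume:
    """Map intensities onto [0, 1]: affine inside the window, clipped outside."""
    lo = window.level - window.width / 2.0
    out = np.clip((vol.data.astype(float) - lo) / window.width, 0.0, 1.0)
    return ImageVolume(data=out, spacing=vol.spacing, origin=vol.origin)


def percentile_window(
    vol: ImageVolume, lower: float = 1.0, upper: float = 99.0, nonzero: bool = True
) -> WindowSpec:
    """Robust window from intensity percentiles (of nonzero voxels by default).

    The fallback normalization for modalities without a conventional window
    (MR arbitrary units, PET uptake).
    """
    data = vol.data
    if nonzero:
        sel = data[data != 0]
        data = sel if sel.size else data
    lo, hi = np.percentile(data, (lower, upper))
    if hi <= lo:  # flat image: any window works, use unit width around it
        return WindowSpec(level=float(lo), width=1.0)
    return WindowSpec(level=float((lo + hi) / 2.0), width=float(hi - lo))


def mask_volume_cm3(mask: GTVMask) -> float:
    """Volume of a mask in cm^3: (true voxel count) x voxel volume."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0
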