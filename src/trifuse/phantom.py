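"""Seeded synthetic tri-modality phantoms and simulated observer contours.

The generator emulates a co-registered head acquisition with one
ellipsoidal lesion:

* **CT-like** volume: air background, a brain-tissue head ellipsoid wrapped in
  a high-attenuation skull shell, a mildly hyperdense lesion (HU scale).
* **MR-like** (contrast-enhanced T1-ish) volume: arbitrary units, brain
  parenchyma with a lesion whose rim is brightened by an enhancement factor,
  dark bone.
* **PET-like** volume: uniform background uptake in the head with a focal
  lesion whose uptake is ``uptake_ratio`` times background.

Observer delineations are simulated from the ground-truth lesion by moving
its surface along the local normal by a smooth random radial field (band
limited spherical harmonics of the viewing direction from the lesion
centroid) plus a per-observer systematic margin, then re-digitizing.  All
randomness flows from the spec's single integer seed; observer ``i`` draws
from sub-seed ``seed + i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, special

from .errors import ParameterError, SimulationError
from .masks import MaskSet
from .volumes import GridSpec, GTVMask, ImageVolume

__all__ = ["PhantomSpec", "ObserverSpec", "generate_phantom", "simulate_observers"]


def _default_grid() -> GridSpec:
    # 128^3 at 2 mm, centered on the world origin
    shape = (128, 128, 128)
    spacing = (2.0, 2.0, 2.0)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return GridSpec(shape, spacing, origin)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of the synthetic tri-modality study."""

    grid: GridSpec = field(default_factory=_default_grid)
    lesion_center_mm: tuple[float, float, float] = (25.0, 10.0, 15.0)
    lesion_radii_mm: tuple[float, float, float] = (20.0, 17.0, 14.0)
    head_radii_mm: tuple[float, float, float] = (80.0, 95.0, 85.0)
    skull_thickness_mm: float = 6.0
    # CT contrast (HU)
    ct_air_hu: float = -1000.0
    ct_brain_hu: float = 40.0
    ct_skull_hu: float = 1000.0
    ct_lesion_hu: float = 60.0
    # MR contrast (arbitrary units)
    mr_brain: float = 400.0
    mr_bone: float = 100.0
    mr_lesion: float = 450.0
    mr_rim_enhancement: float = 1.8  # rim intensity = factor x brain
    mr_rim_thickness_mm: float = 3.0
    # PET contrast (background-normalized uptake)
    pet_background: float = 1.0
    pet_uptake_ratio: float = 4.0
    # additive Gaussian noise SD per modality (modality units)
    ct_noise_hu: float = 15.0
    mr_noise: float = 15.0
    pet_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.lesion_radii_mm):
            raise ParameterError("lesion radii must be positive")
        if self.pet_uptake_ratio < 1.0:
            raise ParameterError("PET uptake ratio must be >= 1")
        lo, hi = self.grid.world_extent()
        c = np.asarray(self.lesion_center_mm)
        r = np.asarray(self.lesion_radii_mm)
        if np.any(c - r <= lo) or np.any(c + r >= hi):
            raise ParameterError("lesion must lie strictly inside the grid")


@dataclass(frozen=True)
class ObserverSpec:
    """How simulated observers disagree about the ground-truth lesion."""

    n_observers: int = 3
    radial_sd_mm: float = 2.0  # SD of the smooth random surface displacement
    band_limit: int = 4  # spherical-harmonic degree cap (smoothness)
    margins_mm: tuple[float, ...] = ()  # systematic margin per observer (0 if empty)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ParameterError("need at least one observer")
        if self.radial_sd_mm < 0:
            raise ParameterError("radial perturbation SD must be >= 0")
        if self.band_limit < 1:
            raise ParameterError("band limit must be >= 1")
        if self.margins_mm and len(self.margins_mm) != self.n_observers:
            raise ParameterError("one margin per observer (or none)")

    def margin(self, i: int) -> float:
        return self.margins_mm[i] if self.margins_mm else 0.0


def _world_coordinates(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        grid.origin[k] + np.arange(grid.shape[k]) * grid.spacing[k] for k in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_norm(
    grid: GridSpec, center: Sequence[float], radii: Sequence[float]
) -> np.ndarray:
    """sqrt(sum(((x-c)/r)^2)) on the grid; <= 1 inside the ellipsoid."""
    X, Y, Z = _world_coordinates(grid)
    c = np.asarray(center, dtype=float)
    r = np.asarray(radii, dtype=float)
    return np.sqrt(
        ((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2 + ((Z - c[2]) / r[2]) ** 2
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, GTVMask]:
    """Build (ct, mr, pet, truth) deterministically from ``spec.seed``.

    The truth mask is the exact voxel-center digitization of the lesion
    ellipsoid; the three volumes carry the lesion with the specified contrast
    plus additive Gaussian noise per modality.
    """
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)

    head = _ellipsoid_norm(grid, (0.0, 0.0, 0.0), spec.head_radii_mm)
    inner_scale = 1.0 - spec.skull_thickness_mm / float(np.min(spec.head_radii_mm))
    brain = head <= inner_scale
    skull = (head <= 1.0) & ~brain
    lesion_norm = _ellipsoid_norm(grid, spec.lesion_center_mm, spec.lesion_radii_mm)
    lesion = lesion_norm <= 1.0
    truth = GTVMask(data=lesion, grid=grid)

    ct = np.full(grid.shape, spec.ct_air_hu)
    ct[brain] = spec.ct_brain_hu
    ct[skull] = spec.ct_skull_hu
    ct[lesion] = spec.ct_lesion_hu

    # MR: enhanced rim = lesion shell within rim_thickness of the boundary
    rim_scale = np.asarray(spec.lesion_radii_mm) - spec.mr_rim_thickness_mm
    if np.any(rim_scale <= 0):
        raise ParameterError("rim thickness larger than a lesion radius")
    core = _ellipsoid_norm(grid, spec.lesion_center_mm, rim_scale) <= 1.0
    rim = lesion & ~core
    mr = np.zeros(grid.shape)
    mr[brain] = spec.mr_brain
    mr[skull] = spec.mr_bone
    mr[lesion] = spec.mr_lesion
    mr[rim] = spec.mr_rim_enhancement * spec.mr_brain

    pet = np.zeros(grid.shape)
    in_head = head <= 1.0
    pet[in_head] = spec.pet_background
    pet[lesion] = spec.pet_uptake_ratio * spec.pet_background

    if spec.ct_noise_hu > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_hu, grid.shape)
    if spec.mr_noise > 0:
        mr = mr + rng.normal(0.0, spec.mr_noise, grid.shape)
    if spec.pet_noise > 0:
        pet = pet + rng.normal(0.0, spec.pet_noise, grid.shape)

    mk = lambda a: ImageVolume(data=a, spacing=grid.spacing, origin=grid.origin)
    return mk(ct), mk(mr), mk(pet), truth


# ---------------------------------------------------------------------------
# Observer simulation
# ---------------------------------------------------------------------------

def _real_sph_harm_basis(
    theta: np.ndarray, phi: np.ndarray, band_limit: int
) -> np.ndarray:
    """Real orthonormal spherical harmonics Y_lm for l = 1..band_limit.

    ``theta`` is the polar angle (from +z), ``phi`` the azimuth.  Returns an
    array of shape (n_harmonics, *theta.shape).  With iid N(0,1) coefficients
    the resulting random field has pointwise variance
    sum_l (2l+1)/(4pi) = (L^2 + 2L)/(4pi) by the addition theorem, which is
    used to normalize the field to a requested SD.
    """
    out = []
    for l in range(1, band_limit + 1):
        out.append(special.sph_harm_y(l, 0, theta, phi).real)
        for m in range(1, l + 1):
            ylm = special.sph_harm_y(l, m, theta, phi)
            sign = (-1.0) ** m
            out.append(np.sqrt(2.0) * sign * ylm.real)
            out.append(np.sqrt(2.0) * sign * ylm.imag)
    return np.stack(out)


def _smooth_radial_field(
    directions_theta_phi: tuple[np.ndarray, np.ndarray],
    sd_mm: float,
    band_limit: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited random field on the sphere with pointwise SD ``sd_mm``."""
    theta, phi = directions_theta_phi
    basis = _real_sph_harm_basis(theta, phi, band_limit)
    coeff = rng.normal(size=len(basis))
    raw = np.tensordot(coeff, basis, axes=1)
    variance = (band_limit**2 + 2 * band_limit) / (4.0 * np.pi)
    return sd_mm * raw / np.sqrt(variance)


def _signed_distance_mm(mask: GTVMask, band_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Signed distance (mm, positive outside) to the mask's 0.5 iso-surface.

    Exact point-to-mesh distances are computed only inside a band of
    ``band_mm`` around the surface (voxel-center distance transforms are too
    quantized to place a shifted contour accurately); outside the band the
    distance is set to +/- inf, which is all the observer simulation needs.
    Returns ``(sdist, band)``.
    """
    import trimesh

    from .surfaces import extract_surface

    sp = np.asarray(mask.grid.spacing)
    rough = ndimage.distance_transform_edt(
        ~mask.data, sampling=sp
    ) - ndimage.distance_transform_edt(mask.data, sampling=sp)
    band = np.abs(rough) <= band_mm + 2.0 * float(sp.max())

    mesh = extract_surface(mask)
    tri = mesh.triangles
    idx = np.argwhere(band)
    pts = np.asarray(mask.grid.origin) + idx * sp

    # nearest-centroid candidates via KD-tree, exact distance on candidates:
    # k covers any triangle whose true distance beats the best centroid hit
    # because marching-cubes triangles are at most ~one voxel across
    from scipy.spatial import cKDTree

    k = min(24, len(tri))
    _, cand = cKDTree(mesh.triangles_center).query(pts, k=k)
    cand = np.atleast_2d(cand)
    flat_tri = tri[cand.ravel()]
    flat_pts = np.repeat(pts, k, axis=0)
    closest = trimesh.triangles.closest_point(flat_tri, flat_pts)
    d = np.linalg.norm(closest - flat_pts, axis=1).reshape(len(pts), k)
    dist = d.min(axis=1)

    sdist = np.where(mask.data, -np.inf, np.inf)
    sign = np.where(mask.data[band], -1.0, 1.0)
    sdist[band] = sign * dist
    return sdist, band


def simulate_observers(truth: GTVMask, spec: ObserverSpec) -> MaskSet:
    """Simulate observer delineations of ``truth``.

    Each observer's mask is the set ``{x : sdist(x) <= margin_i + f_i(u(x))}``
    where ``sdist`` is the signed distance to the truth surface, ``u(x)`` the
    direction from the truth centroid, and ``f_i`` the observer's smooth
    random radial field (SD ``radial_sd_mm``).  With zero SD and zero margin
    every observer reproduces the truth exactly.
    """
    if truth.is_empty():
        raise SimulationError("truth mask is empty")
    grid = truth.grid
    idx = np.argwhere(truth.data)
    centroid = np.asarray(grid.origin) + idx.mean(axis=0) * np.asarray(grid.spacing)

    # Only voxels near the surface can change membership (4 SD covers the
    # random field; voxels beyond the band keep their truth membership)
    max_shift = abs(spec.radial_sd_mm) * 4.0 + max(
        (abs(m) for m in spec.margins_mm), default=0.0
    )
    sdist, band = _signed_distance_mm(truth, max_shift)

    X, Y, Z = _world_coordinates(grid)
    dx = X[band] - centroid[0]
    dy = Y[band] - centroid[1]
    dz = Z[band] - centroid[2]
    rho = np.sqrt(dx**2 + dy**2 + dz**2)
    rho = np.where(rho < 1e-9, 1e-9, rho)
    theta = np.arccos(np.clip(dz / rho, -1.0, 1.0))
    phi = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)

    masks = []
    for i in range(spec.n_observers):
        rng = np.random.default_rng(spec.seed + i)
        data = truth.data.copy()
        offset = np.full(band.sum(), spec.margin(i))
        if spec.radial_sd_mm > 0:
            offset = offset + _smooth_radial_field(
                (theta, phi), spec.radial_sd_mm, spec.band_limit, rng
            )
        data[band] = sdist[band] <= offset
        if not data.any():
            raise SimulationError(f"observer {i} mask perturbed into emptiness")
        masks.append(GTVMask(data=data, grid=grid))
    return MaskSet(masks, labels=[f"obs{i + 1}" for i in range(spec.n_observers)])
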