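"""Tri-modality transparency-weighted fusion.

CT is the opaque background layer; MR and PET are semi-transparent foreground
layers composited back-to-front (PET over MR over CT):

    I_mix = t_P * I_PET + (1 - t_P) * [ t_M * I_MR + (1 - t_M) * I_CT ]

with transparency factors ``t_P``, ``t_M`` in [0, 1].  ``t = 1`` means the
layer is fully shown (pure PET at ``t_P = 1``, pure MR at ``t_P = 0, t_M = 1``,
pure CT at ``t_P = t_M = 0``).  For normalized inputs every output voxel is a
convex combination of the three inputs: the weights ``t_P``,
``(1 - t_P) t_M``, ``(1 - t_P)(1 - t_M)`` are nonnegative and sum to 1 for any
setting, so the fused image stays in [0, 1] over the whole transparency square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .volumes import GridSpec, ImageVolume

__all__ = ["TransparencyPair", "FusedVolume", "fuse", "fuse_slice"]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class TransparencyPair:
    """User-set PET and MR transparency factors, each in [0, 1]."""

    t_p: float
    t_m: float

    def __post_init__(self) -> None:
        for name, value in (("t_p", self.t_p), ("t_m", self.t_m)):
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {value}")

    @property
    def weights(self) -> tuple[float, float, float]:
        """Convex weights (w_PET, w_MR, w_CT); they sum to 1."""
        return (
            self.t_p,
            (1.0 - self.t_p) * self.t_m,
            (1.0 - self.t_p) * (1.0 - self.t_m),
        )


@dataclass
class FusedVolume:
    """The fused image I_mix on the primary (CT) grid, values in [0, 1]."""

    volume: ImageVolume
    transparency: TransparencyPair

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def grid(self) -> GridSpec:
        return self.volume.grid


def _check_normalized(name: str, vol: ImageVolume) -> None:
    data = vol.data
    if data.size and (data.min() < -_UNIT_TOL or data.max() > 1.0 + _UNIT_TOL):
        raise ParameterError(
            f"{name} intensities must be window-normalized to [0, 1] before fusion "
            f"(range [{data.min():.4g}, {data.max():.4g}])"
        )


def fuse(
    ct: ImageVolume,
    mr: ImageVolume,
    pet: ImageVolume,
    t: TransparencyPair,
) -> FusedVolume:
    """Composite normalized CT/MR/PET volumes under transparency factors.

    All three volumes must share one grid (co-registered and resampled) and be
    normalized to [0, 1].  The result is affine in each transparency factor and
    bounded by the inputs voxelwise.
    """
    if not (ct.grid.same_as(mr.grid) and ct.grid.same_as(pet.grid)):
        raise GeometryError("CT, MR and PET must be resampled onto one common grid")
    for name, vol in (("CT", ct), ("MR", mr), ("PET", pet)):
        _check_normalized(name, vol)

    w_pet, w_mr, w_ct = t.weights
    mix = w_pet * pet.data + w_mr * mr.data + w_ct * ct.data
    # convex combination of [0,1] inputs; clip only to shed float round-off
    np.clip(mix, 0.0, 1.0, out=mix)
    fused = ImageVolume(data=mix, spacing=ct.spacing, origin=ct.origin)
    return FusedVolume(volume=fused, transparency=t)


def fuse_slice(
    ct: ImageVolume,
    mr: ImageVolume,
    pet: ImageVolume,
    t: TransparencyPair,
    axis: int,
    index: int,
) -> np.ndarray:
    """One 2D slice of the fused volume, for preview/export.

    Equals ``fuse(...).data`` sliced along ``axis`` at ``index``.
    """
    if axis not in (0, 1, 2):
        raise IndexError(f"axis must be 0, 1 or 2, got {axis}")
    n = ct.data.shape[axis]
    if not 0 <= index < n:
        raise IndexError(f"slice index {index} out of range [0, {n}) on axis {axis}")

    def take(vol: ImageVolume) -> ImageVolume:
        sl = np.take(vol.data, index, axis=axis)[..., np.newaxis]
        return ImageVolume(data=sl, spacing=vol.spacing, origin=vol.origin)

    fused = fuse(take(ct), take(mr), take(pet), t)
    return fused.data[..., 0]
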