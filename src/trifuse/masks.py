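"""Boolean algebra on GTV masks.

These operations implement the volume-combination steps of a multi-modality
delineation protocol: the overlap of the CT/MRI-based GTV with the PET-based
GTV (``GTV_common``), and the final GTV assembled from that overlap plus the
parts of each single-scheme GTV the observer decided to keep.  Which parts to
keep is clinical judgment and therefore an *input* mask, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ProtocolError
from .volumes import GridSpec, GTVMask, _require_same_grid

__all__ = ["MaskSet", "intersect", "union", "subtract", "compose_final_gtv"]


@dataclass
class MaskSet:
    """An ordered collection of masks on one grid with unique labels."""

    masks: list[GTVMask]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.masks:
            raise GeometryError("MaskSet needs at least one mask")
        if not self.labels:
            self.labels = [f"obs{i + 1}" for i in range(len(self.masks))]
        if len(self.labels) != len(self.masks):
            raise GeometryError("one label per mask required")
        if len(set(self.labels)) != len(self.labels):
            raise GeometryError(f"labels must be unique, got {self.labels}")
        g = self.masks[0].grid
        for m in self.masks[1:]:
            _require_same_grid(g, m.grid, "masks in a MaskSet")

    @property
    def grid(self) -> GridSpec:
        return self.masks[0].grid

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def stack(self) -> np.ndarray:
        """Boolean array of shape (n_masks, nx, ny, nz)."""
        return np.stack([m.data for m in self.masks])


def _binary_op(a: GTVMask, b: GTVMask, op) -> GTVMask:
    _require_same_grid(a.grid, b.grid, "mask operands")
    return GTVMask(data=op(a.data, b.data), grid=a.grid)


def intersect(a: GTVMask, b: GTVMask) -> GTVMask:
    """Voxelwise AND — the region delineated in both schemes (GTV_common)."""
    return _binary_op(a, b, np.logical_and)


def union(a: GTVMask, b: GTVMask) -> GTVMask:
    """Voxelwise OR."""
    return _binary_op(a, b, np.logical_or)


def subtract(a: GTVMask, b: GTVMask) -> GTVMask:
    """Voxelwise AND-NOT — the part of ``a`` outside ``b``."""
    return _binary_op(a, b, lambda x, y: np.logical_and(x, np.logical_not(y)))


def compose_final_gtv(
    gtv_mrict: GTVMask,
    gtv_pet: GTVMask,
    keep_from_mrict: GTVMask,
    keep_from_pet: GTVMask,
) -> GTVMask:
    """Assemble the final tri-modality GTV.

    ``final = (gtv_mrict & gtv_pet) | keep_from_mrict | keep_from_pet`` where
    the kept parts are the observer-chosen subsets of the respective exclusive
    regions (``gtv_mrict - gtv_pet`` and ``gtv_pet - gtv_mrict``).  The result
    always lies between GTV_common and the union of the two input GTVs.
    """
    only_mrict = subtract(gtv_mrict, gtv_pet)
    only_pet = subtract(gtv_pet, gtv_mrict)
    if np.any(keep_from_mrict.data & ~only_mrict.data):
        raise ProtocolError(
            "keep_from_mrict must be a subset of gtv_mrict outside gtv_pet"
        )
    if np.any(keep_from_pet.data & ~only_pet.data):
        raise ProtocolError(
            "keep_from_pet must be a subset of gtv_pet outside gtv_mrict"
        )
    common = intersect(gtv_mrict, gtv_pet)
    return union(union(common, keep_from_mrict), keep_from_pet)
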