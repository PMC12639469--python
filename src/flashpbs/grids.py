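"""Volumetric containers: scalar voxel grids and binary structure sets.

A :class:`VoxelGrid` is a 3-D scalar field (relative density, dose in Gy,
or dose rate in Gy/s) with isotropic-or-not voxel spacing and a world-space
origin.  World coordinates are millimetres at voxel centers: the center of
voxel ``(i, j, k)`` sits at ``origin_mm + (i, j, k) * spacing_mm``.

A :class:`StructureSet` holds named binary masks (one PTV, one BODY, any
number of OARs) congruent with a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "StructureSet",
    "read_grid",
    "write_grid",
    "GridFormatError",
]


class GridFormatError(ValueError):
    """Raised when a volumetric file does not hold a 3-D scalar grid."""


@dataclass
class VoxelGrid:
    """A 3-D scalar field with spacing/origin metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar per voxel. Units depend on role (unitless relative density,
        Gy, or Gy/s).
    spacing_mm : tuple of 3 floats
        Voxel pitch along each axis, strictly positive.
    origin_mm : tuple of 3 floats
        World coordinate of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GridFormatError(
                f"VoxelGrid requires 3-D data, got {self.values.ndim}-D"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be > 0, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid sharing this grid's geometry but holding ``values``."""
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError(
                f"shape mismatch: {values.shape} vs {self.values.shape}"
            )
        return VoxelGrid(values, self.spacing_mm, self.origin_mm)

    def zeros_like(self, dtype=np.float64) -> "VoxelGrid":
        return self.like(np.zeros(self.values.shape, dtype=dtype))

    def congruent(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        """Same dims, spacing and origin (within float tolerance)."""
        return (
            self.dims == other.dims
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def require_congruent(self, other: "VoxelGrid") -> None:
        if not self.congruent(other):
            raise ValueError("grids are not congruent (dims/spacing/origin differ)")

    def voxel_centers_mm(self, flat_index: np.ndarray) -> np.ndarray:
        """World coordinates (N, 3) of voxels given flat (C-order) indices."""
        idx = np.column_stack(np.unravel_index(np.asarray(flat_index), self.dims))
        return idx * np.asarray(self.spacing_mm) + np.asarray(self.origin_mm)

    def index_coords(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points (N, 3)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


@dataclass
class StructureSet:
    """Named binary masks on a common grid.

    Must contain a non-empty ``PTV`` and a ``BODY`` mask; every other mask
    is treated as an OAR.  All masks are subsets of BODY.
    """

    grid: VoxelGrid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.grid.dims:
                raise ValueError(
                    f"mask '{name}' shape {m.shape} incongruent with grid {self.grid.dims}"
                )
            self.masks[name] = m
        if "PTV" not in self.masks or "BODY" not in self.masks:
            raise ValueError("StructureSet requires 'PTV' and 'BODY' masks")
        if not self.masks["PTV"].any():
            raise ValueError("PTV mask is empty")
        body = self.masks["BODY"]
        for name, m in self.masks.items():
            if name != "BODY" and np.any(m & ~body):
                raise ValueError(f"mask '{name}' is not contained in BODY")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    @property
    def ptv(self) -> np.ndarray:
        return self.masks["PTV"]

    @property
    def body(self) -> np.ndarray:
        return self.masks["BODY"]

    @property
    def oar_names(self) -> Tuple[str, ...]:
        return tuple(n for n in self.masks if n not in ("PTV", "BODY"))

    def volume_cm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_mm3 / 1000.0


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def write_grid(grid: VoxelGrid, path) -> None:
    """Write a grid as a NIfTI volume (spacing/origin in the affine)."""
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float64), _affine(grid))
    nib.save(img, str(path))


def read_grid(path) -> VoxelGrid:
    """Read a 3-D NIfTI volume back into a :class:`VoxelGrid`.

    Raises
    ------
    GridFormatError
        If the file does not contain 3-D scalar data or a diagonal affine.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise GridFormatError(f"{path}: expected 3-D data, got {data.ndim}-D")
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise GridFormatError(f"{path}: non-positive voxel spacing in affine")
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(data, spacing, origin)
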