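"""Synthetic phantoms emulating four clinical geometry classes.

Patient CT data for transmission-beam FLASH planning studies are not
shareable, so every downstream stage here is exercised on procedurally
generated phantoms.  Four presets span the geometry space that drives
pulse-repetition-frequency (PRF) findings for scanned beams:

- ``brain_like``    small, shallow spherical target;
- ``lung_like``     small target embedded in low-density (0.3) surroundings;
- ``liver_like``    large target;
- ``prostate_like`` large, deep target with two abutting box OARs.

Target volumes are ordered brain < lung < liver <= prostate, mirroring the
small-vs-large-target dichotomy in scanned-delivery dose-rate coverage.
Densities are relative to water (water = 1.0, air = 0.0); there is no CT
calibration curve, and BODY is a simple box.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grids import StructureSet, VoxelGrid

__all__ = ["PhantomSpec", "OarSpec", "DensityInsert", "InvalidSpecError",
           "generate_phantom", "PRESETS", "preset_spec"]


class InvalidSpecError(ValueError):
    """Raised for degenerate or inconsistent phantom specifications."""


@dataclass
class OarSpec:
    """A box- or sphere-shaped organ at risk, placed relative to the target."""

    name: str
    shape: str = "box"                      # "box" | "sphere"
    size_mm: Tuple[float, float, float] = (30.0, 30.0, 30.0)  # full box edges, or (r,r,r)
    offset_mm: Tuple[float, float, float] = (0.0, 40.0, 0.0)  # from target center


@dataclass
class DensityInsert:
    """An ellipsoidal region of non-water relative density (e.g. lung)."""

    center_mm: Tuple[float, float, float]
    semi_axes_mm: Tuple[float, float, float]
    density: float


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom.

    ``target_depth_mm`` measures from the -y BODY face (the entry side of a
    0-degree beam) to the target center; when ``None`` the target sits at
    ``target_center_mm``.
    """

    preset: str = "custom"
    dims: Tuple[int, int, int] = (100, 100, 100)
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_margin_mm: float = 10.0
    target_radius_mm: float = 20.0
    target_center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_depth_mm: Optional[float] = None
    oars: List[OarSpec] = field(default_factory=list)
    inserts: List[DensityInsert] = field(default_factory=list)
    body_density: float = 1.0
    air_density: float = 0.0
    seed: int = 0
    field_angles_deg: Tuple[float, ...] = (0.0,)
    prescription_Gy: float = 30.0
    fractions: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _brain_like() -> PhantomSpec:
    return PhantomSpec(
        preset="brain_like",
        target_radius_mm=15.0,
        target_depth_mm=40.0,
        oars=[OarSpec("brainstem_like", "box", (24.0, 24.0, 24.0), (0.0, 34.0, 0.0))],
        field_angles_deg=(0.0,),
    )


def _lung_like() -> PhantomSpec:
    return PhantomSpec(
        preset="lung_like",
        target_radius_mm=20.0,
        target_center_mm=(0.0, -20.0, 0.0),
        inserts=[DensityInsert((0.0, -10.0, 0.0), (50.0, 60.0, 60.0), 0.3)],
        oars=[OarSpec("heart_like", "box", (40.0, 40.0, 40.0), (50.0, 10.0, 0.0))],
        field_angles_deg=(0.0, 90.0),
    )


def _liver_like() -> PhantomSpec:
    return PhantomSpec(
        preset="liver_like",
        target_radius_mm=40.0,
        oars=[OarSpec("cord_like", "box", (25.0, 25.0, 60.0), (0.0, 55.0, 0.0))],
        field_angles_deg=(0.0, 270.0),
    )


def _prostate_like() -> PhantomSpec:
    # Two OARs abutting the target surface along +-y (bladder/rectum analogue).
    return PhantomSpec(
        preset="prostate_like",
        target_radius_mm=40.0,
        oars=[
            OarSpec("bladder_like", "box", (50.0, 30.0, 40.0), (0.0, -55.0, 0.0)),
            OarSpec("rectum_like", "box", (30.0, 30.0, 40.0), (0.0, 55.0, 0.0)),
        ],
        field_angles_deg=(90.0, 270.0),
    )


PRESETS = {
    "brain_like": _brain_like,
    "lung_like": _lung_like,
    "liver_like": _liver_like,
    "prostate_like": _prostate_like,
}


def preset_spec(name: str, **overrides) -> PhantomSpec:
    """Return the spec for a named preset, optionally overriding fields."""
    if name not in PRESETS:
        raise InvalidSpecError(
            f"unknown preset '{name}'; choose from {sorted(PRESETS)}"
        )
    spec = PRESETS[name]()
    return dataclasses.replace(spec, **overrides) if overrides else spec


def _world_axes(spec: PhantomSpec):
    dims = np.asarray(spec.dims)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    origin = -(dims - 1) / 2.0 * spacing  # grid centered on the world origin
    axes = [origin[a] + spacing[a] * np.arange(dims[a]) for a in range(3)]
    return origin, np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return (
        ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    ) <= 1.0


def _box_mask(coords, center, size) -> np.ndarray:
    x, y, z = coords
    h = np.asarray(size, dtype=float) / 2.0
    return (
        (np.abs(x - center[0]) <= h[0])
        & (np.abs(y - center[1]) <= h[1])
        & (np.abs(z - center[2]) <= h[2])
    )


def generate_phantom(spec: PhantomSpec) -> Tuple[VoxelGrid, StructureSet]:
    """Generate the density grid and structure set for a phantom spec.

    Deterministic for a fixed spec (the seed is recorded in the spec and
    threads through any stochastic downstream stage, e.g. spot-placement
    initialization).

    Raises
    ------
    InvalidSpecError
        Degenerate target (radius smaller than one voxel) or a target that
        does not fit inside BODY.
    """
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    if spec.target_radius_mm < float(spacing.min()):
        raise InvalidSpecError(
            f"target radius {spec.target_radius_mm} mm is smaller than one voxel"
        )
    if spec.body_density <= 0:
        raise InvalidSpecError("body density must be > 0")
    for ins in spec.inserts:
        if ins.density <= 0:
            raise InvalidSpecError("insert densities must be > 0")

    origin, coords = _world_axes(spec)
    extent = (np.asarray(spec.dims) - 1) / 2.0 * spacing
    body_half = extent - spec.body_margin_mm
    if np.any(body_half <= 0):
        raise InvalidSpecError("body margin leaves no BODY volume")

    body = _box_mask(coords, (0.0, 0.0, 0.0), 2.0 * body_half)

    center = np.asarray(spec.target_center_mm, dtype=float)
    if spec.target_depth_mm is not None:
        # Depth measured from the -y BODY face along +y.
        center = center.copy()
        center[1] = -body_half[1] + spec.target_depth_mm
    r = spec.target_radius_mm
    if np.any(np.abs(center) + r > body_half):
        raise InvalidSpecError("target does not fit inside BODY")
    ptv = _ellipsoid_mask(coords, center, (r, r, r))

    density = np.full(spec.dims, spec.air_density, dtype=np.float64)
    density[body] = spec.body_density
    for ins in spec.inserts:
        m = _ellipsoid_mask(coords, ins.center_mm, ins.semi_axes_mm) & body
        density[m] = ins.density
    density[ptv] = spec.body_density  # target is always water-like

    masks: Dict[str, np.ndarray] = {"BODY": body, "PTV": ptv}
    for oar in spec.oars:
        oc = center + np.asarray(oar.offset_mm, dtype=float)
        if oar.shape == "box":
            m = _box_mask(coords, oc, oar.size_mm)
        elif oar.shape == "sphere":
            m = _ellipsoid_mask(coords, oc, oar.size_mm)
        else:
            raise InvalidSpecError(f"unknown OAR shape '{oar.shape}'")
        m &= body
        if not m.any():
            raise InvalidSpecError(f"OAR '{oar.name}' is empty inside BODY")
        masks[oar.name] = m

    grid = VoxelGrid(density, tuple(spacing), tuple(origin))
    return grid, StructureSet(grid, masks)
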