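"""Analytic transmission pencil-beam kernels for protons and VHEE.

Transmission ("shoot-through") beams traverse the patient at the machine's
highest energy, so the dose of a single scanned spot factorizes into a
slowly varying depth-dose along the ray and a lateral (double-)Gaussian
profile that broadens with depth:

    dose(voxel) = calibration * PDD(z_rad) * L(r_perp, z_rad)

with ``z_rad`` the radiological depth (line integral of relative density
from the body entry to the voxel) and ``L`` a normalized 2-D Gaussian
mixture, ``sigma_i(z) = sigma_i0 + growth * z``.

These kernels deliberately replace full transport engines: the plan-level
quantities studied here (dose-rate coverage, FLASH index, PRF thresholds)
are governed by delivery timing and geometry, not sub-percent dosimetry.
Depth-dose tables are plain (depth, value) arrays and fully configurable.

Coordinate convention: the gantry angle ``g`` (degrees) rotates the beam in
the axial x-y plane about the isocenter.  The beam travels along
``d = (sin g, cos g, 0)`` (a 0-degree field enters from -y); beam's-eye-view
(BEV) axes are ``e_u = (cos g, -sin g, 0)`` and ``e_v = (0, 0, 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates

from .grids import VoxelGrid

__all__ = [
    "LateralProfile",
    "BeamModel",
    "FieldGeometry",
    "BeamTransport",
    "radiological_depth",
    "spot_dose_column",
    "default_proton_model",
    "default_vhee_model",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.355


@dataclass
class LateralProfile:
    """Single- or double-Gaussian lateral fluence profile.

    The profile integrates to 1 over the transverse plane at every depth;
    both components share the linear broadening rate
    ``sigma_growth_mm_per_mm`` (multiple-Coulomb-scattering surrogate).
    """

    kind: str = "single_gaussian"       # "single_gaussian" | "double_gaussian"
    sigma1_mm: float = 5.0
    sigma2_mm: Optional[float] = None   # required for double_gaussian, > sigma1
    weight1: float = 1.0                # in (0, 1]; weight2 = 1 - weight1
    sigma_growth_mm_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma1_mm <= 0:
            raise ValueError("sigma1_mm must be > 0")
        if self.sigma_growth_mm_per_mm < 0:
            raise ValueError("sigma growth must be >= 0")
        if not (0.0 < self.weight1 <= 1.0):
            raise ValueError("weight1 must be in (0, 1]")
        if self.kind == "double_gaussian":
            if self.sigma2_mm is None or self.sigma2_mm <= self.sigma1_mm:
                raise ValueError("double_gaussian requires sigma2_mm > sigma1_mm")
        elif self.kind == "single_gaussian":
            self.weight1 = 1.0
        else:
            raise ValueError(f"unknown lateral profile kind '{self.kind}'")

    @property
    def weight2(self) -> float:
        return 1.0 - self.weight1

    def sigmas_at(self, depth_mm: np.ndarray) -> Tuple[np.ndarray, Optional[np.ndarray]]:
        g = self.sigma_growth_mm_per_mm
        s1 = self.sigma1_mm + g * depth_mm
        s2 = self.sigma2_mm + g * depth_mm if self.sigma2_mm is not None else None
        return s1, s2

    def value(self, r2_mm2: np.ndarray, depth_mm: np.ndarray) -> np.ndarray:
        """Profile value (mm^-2) at squared radius ``r2`` and depth."""
        s1, s2 = self.sigmas_at(np.asarray(depth_mm, dtype=float))
        v1 = s1 * s1
        out = (self.weight1 / (2.0 * np.pi * v1)) * np.exp(-0.5 * r2_mm2 / v1)
        if self.kind == "double_gaussian" and self.weight2 > 0:
            v2 = s2 * s2
            out = out + (self.weight2 / (2.0 * np.pi * v2)) * np.exp(
                -0.5 * r2_mm2 / v2
            )
        return out

    def max_sigma(self, depth_mm: float) -> float:
        s1, s2 = self.sigmas_at(np.asarray(depth_mm, dtype=float))
        return float(s2 if s2 is not None else s1)


@dataclass
class BeamModel:
    """Particle species + lateral profile + tabulated normalized depth-dose.

    ``calibration_Gy_per_MU`` converts monitor units to dose at profile
    normalization scale (Gy mm^2 / MU): an on-axis voxel receives
    ``calibration * pdd(z) * L(0, z)`` Gy per MU.
    """

    particle: str                        # "proton" | "electron"
    energy_MeV: float
    lateral: LateralProfile
    pdd_depth_mm: Sequence[float] = (0.0, 400.0)
    pdd_value: Sequence[float] = (1.0, 1.0)
    calibration_Gy_per_MU: float = 100.0

    def __post_init__(self) -> None:
        self.pdd_depth_mm = np.asarray(self.pdd_depth_mm, dtype=float)
        self.pdd_value = np.asarray(self.pdd_value, dtype=float)
        if self.pdd_depth_mm.ndim != 1 or self.pdd_depth_mm.shape != self.pdd_value.shape:
            raise ValueError("pdd tables must be matching 1-D arrays")
        if np.any(np.diff(self.pdd_depth_mm) <= 0):
            raise ValueError("pdd depths must be strictly increasing")
        if np.any(self.pdd_value <= 0):
            raise ValueError("pdd values must be > 0 over the tabulated range")
        if self.calibration_Gy_per_MU <= 0:
            raise ValueError("calibration must be > 0")

    def pdd(self, depth_mm: np.ndarray) -> np.ndarray:
        """Piecewise-linear (hence monotone between nodes) PDD lookup."""
        return np.interp(depth_mm, self.pdd_depth_mm, self.pdd_value)


def default_proton_model(energy_MeV: float = 250.0,
                         calibration_Gy_per_MU: float = 100.0) -> BeamModel:
    """250 MeV transmission proton surrogate: single Gaussian, 10 mm FWHM
    in air (sigma0 = FWHM/2.355 = 4.25 mm), mildly rising transmission PDD."""
    return BeamModel(
        particle="proton",
        energy_MeV=energy_MeV,
        lateral=LateralProfile(
            kind="single_gaussian",
            sigma1_mm=10.0 * FWHM_TO_SIGMA,
            sigma_growth_mm_per_mm=0.05,
        ),
        pdd_depth_mm=(0.0, 300.0),
        pdd_value=(0.95, 1.10),
        calibration_Gy_per_MU=calibration_Gy_per_MU,
    )


def default_vhee_model(energy_MeV: float = 200.0,
                       calibration_Gy_per_MU: float = 100.0) -> BeamModel:
    """VHEE transmission surrogate: double Gaussian, sigma1 = 5 mm,
    sigma2 = 3*sigma1, 90% core weight; short build-up then a linear
    decline that is steeper at 150 MeV (-0.7 %/cm) than 200 MeV (-0.4 %/cm)."""
    if energy_MeV not in (150.0, 200.0):
        raise ValueError("default VHEE models are tabulated at 150 and 200 MeV")
    slope_per_mm = 7e-4 if energy_MeV == 150.0 else 4e-4
    growth = 0.10 if energy_MeV == 150.0 else 0.07
    return BeamModel(
        particle="electron",
        energy_MeV=energy_MeV,
        lateral=LateralProfile(
            kind="double_gaussian",
            sigma1_mm=5.0,
            sigma2_mm=15.0,
            weight1=0.9,
            sigma_growth_mm_per_mm=growth,
        ),
        pdd_depth_mm=(0.0, 30.0, 300.0),
        pdd_value=(0.85, 1.0, 1.0 - slope_per_mm * 270.0),
        calibration_Gy_per_MU=calibration_Gy_per_MU,
    )


@dataclass
class FieldGeometry:
    """Beam axis in the axial plane: gantry angle about the isocenter."""

    gantry_angle_deg: float = 0.0
    isocenter_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.gantry_angle_deg = float(self.gantry_angle_deg) % 360.0

    @property
    def direction(self) -> np.ndarray:
        g = math.radians(self.gantry_angle_deg)
        return np.array([math.sin(g), math.cos(g), 0.0])

    @property
    def e_u(self) -> np.ndarray:
        g = math.radians(self.gantry_angle_deg)
        return np.array([math.cos(g), -math.sin(g), 0.0])

    @property
    def e_v(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    def bev_coords(self, points_mm: np.ndarray):
        """(u, v, s) of world points: BEV transverse, vertical, along-beam."""
        p = np.atleast_2d(points_mm) - np.asarray(self.isocenter_mm)
        return p @ self.e_u, p @ self.e_v, p @ self.direction


class BeamTransport:
    """Per-field cache of voxel BEV coordinates and radiological depths.

    Radiological depth is the midpoint-rule line integral of relative
    density along the beam axis, sampled at a quarter of the smallest
    voxel spacing (well inside the half-spacing accuracy bound), marching
    from outside the grid (where density samples zero, so the integral
    effectively starts at the body entry) to each voxel center.
    """

    def __init__(self, density: VoxelGrid, geometry: FieldGeometry,
                 voxel_flat_index: Optional[np.ndarray] = None,
                 step_mm: Optional[float] = None):
        self.density = density
        self.geometry = geometry
        if voxel_flat_index is None:
            voxel_flat_index = np.arange(density.n_voxels)
        self.flat_index = np.asarray(voxel_flat_index)
        self.step_mm = float(step_mm) if step_mm else min(density.spacing_mm) / 4.0

        points = density.voxel_centers_mm(self.flat_index)
        self.u, self.v, self.s = geometry.bev_coords(points)
        self.depth_mm = self._march(points)

    def _march(self, points: np.ndarray) -> np.ndarray:
        grid = self.density
        d = self.geometry.direction
        h = self.step_mm
        # Farthest any ray can extend inside the grid.
        corners = np.array(
            [
                [i * (grid.dims[0] - 1), j * (grid.dims[1] - 1), k * (grid.dims[2] - 1)]
                for i in (0, 1) for j in (0, 1) for k in (0, 1)
            ],
            dtype=float,
        ) * np.asarray(grid.spacing_mm) + np.asarray(grid.origin_mm)
        _, _, s_corners = self.geometry.bev_coords(corners)
        s_min = s_corners.min()
        s_pts = self.s
        n_steps = int(np.ceil((s_pts.max() - s_min) / h)) + 1

        spacing = np.asarray(grid.spacing_mm)
        origin = np.asarray(grid.origin_mm)
        depth = np.zeros(points.shape[0])
        # March back toward the source; density outside the grid samples 0.
        for k in range(n_steps):
            sample = points - (k + 0.5) * h * d
            idx = ((sample - origin) / spacing).T
            rho = map_coordinates(grid.values, idx, order=1, mode="constant", cval=0.0)
            depth += rho
        return depth * h

    def column(self, model: BeamModel, spot_bev_mm: Sequence[float],
               truncation_rel: float = 1e-4,
               dtype=np.float64) -> Tuple[np.ndarray, np.ndarray]:
        """Dose per unit weight for one spot over the cached voxels.

        Returns ``(local_indices, values)``: positions into this transport's
        voxel list and dose values (Gy/MU), truncated below
        ``truncation_rel`` of the column maximum.
        """
        x0, y0 = float(spot_bev_mm[0]), float(spot_bev_mm[1])
        lat = model.lateral
        # Conservative candidate radius: where even the widest Gaussian
        # component falls below truncation relative to the core peak.
        max_depth = float(self.depth_mm.max()) if self.depth_mm.size else 0.0
        s_wide = lat.max_sigma(max_depth)
        s1_0 = lat.sigma1_mm
        w_wide = lat.weight2 if lat.kind == "double_gaussian" else lat.weight1
        peak = lat.weight1 / (2.0 * np.pi * s1_0 * s1_0)
        tail_scale = max(w_wide, lat.weight1) / (2.0 * np.pi * s_wide * s_wide)
        arg = tail_scale / (truncation_rel * peak)
        r_cut = s_wide * math.sqrt(2.0 * max(math.log(arg), 1.0)) if arg > 1 else 2 * s_wide

        du = self.u - x0
        dv = self.v - y0
        cand = (np.abs(du) <= r_cut) & (np.abs(dv) <= r_cut)
        cand &= self.depth_mm > 0  # rays that never crossed tissue get no dose
        if not np.any(cand):
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=dtype)
        r2 = du[cand] ** 2 + dv[cand] ** 2
        depth = self.depth_mm[cand]
        vals = model.calibration_Gy_per_MU * model.pdd(depth) * lat.value(r2, depth)
        vmax = vals.max()
        keep = vals >= truncation_rel * vmax
        local = np.flatnonzero(cand)[keep]
        return local, vals[keep].astype(dtype, copy=False)


def radiological_depth(density: VoxelGrid, geometry: FieldGeometry,
                       voxel_index: Sequence[int]) -> float:
    """Water-equivalent depth (mm) of one voxel along the field's beam axis.

    Equals geometric depth in uniform water; 0 for rays that miss all
    tissue (density is zero outside the body).
    """
    voxel_index = tuple(int(i) for i in voxel_index)
    if any(i < 0 or i >= n for i, n in zip(voxel_index, density.dims)):
        raise IndexError(f"voxel {voxel_index} outside grid {density.dims}")
    flat = np.ravel_multi_index(voxel_index, density.dims)
    t = BeamTransport(density, geometry, np.array([flat]))
    return float(t.depth_mm[0])


def spot_dose_column(density: VoxelGrid, geometry: FieldGeometry,
                     model: BeamModel, spot_position_bev_mm: Sequence[float],
                     voxel_flat_index: Optional[np.ndarray] = None,
                     truncation_rel: float = 1e-4) -> sparse.csc_matrix:
    """Sparse dose-per-unit-weight column of one spot over the whole grid.

    Convenience wrapper building a fresh :class:`BeamTransport`; pipelines
    reuse one transport per field instead.  An empty column is returned if
    the spot misses the body.
    """
    transport = BeamTransport(density, geometry, voxel_flat_index)
    local, vals = transport.column(model, spot_position_bev_mm, truncation_rel)
    rows = transport.flat_index[local]
    return sparse.csc_matrix(
        (vals, (rows, np.zeros(len(rows), dtype=np.int64))),
        shape=(density.n_voxels, 1),
    )
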