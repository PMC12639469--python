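"""Spot placement in the beam's-eye view (BEV).

Spots are laid out inside the projected PTV with a centroidal Voronoi
tessellation (Lloyd relaxation of ~one generator per ``spacing**2`` cell)
plus extra spots along the projection contour at ~equal arc-length steps.
The target spacing (default 5 mm) balances the number of scanned spots
against in-target dose homogeneity; border spots substitute for a lateral
margin, which therefore defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .beams import FieldGeometry
from .grids import VoxelGrid

__all__ = [
    "Spot",
    "BevRegion",
    "project_ptv",
    "cvt_interior_spots",
    "border_spots",
    "serpentine_order",
]


@dataclass
class Spot:
    """One scanned pencil-beam spot in BEV coordinates (weight in MU)."""

    bev_x_mm: float
    bev_y_mm: float
    weight: float = 0.0
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")


@dataclass
class BevRegion:
    """Binary BEV mask of the PTV projection plus its closed contour(s).

    ``origin_uv_mm`` is the (u, v) world coordinate of pixel (0, 0)'s
    center; contours are (K, 2) polylines in mm with first == last vertex.
    """

    mask: np.ndarray
    pixel_mm: float
    origin_uv_mm: Tuple[float, float]
    contours: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("BEV region mask must be a non-empty 2-D mask")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_mm ** 2

    def pixel_centers_mm(self) -> np.ndarray:
        """(N, 2) mm coordinates of in-region pixel centers."""
        ij = np.argwhere(self.mask)
        return ij * self.pixel_mm + np.asarray(self.origin_uv_mm)

    def contains_points(self, points_mm: np.ndarray) -> np.ndarray:
        ij = np.rint(
            (np.atleast_2d(points_mm) - np.asarray(self.origin_uv_mm)) / self.pixel_mm
        ).astype(int)
        ok = np.all((ij >= 0) & (ij < self.mask.shape), axis=1)
        out = np.zeros(len(ij), dtype=bool)
        out[ok] = self.mask[ij[ok, 0], ij[ok, 1]]
        return out


def project_ptv(ptv_mask: np.ndarray, grid: VoxelGrid, geometry: FieldGeometry,
                pixel_mm: Optional[float] = None) -> BevRegion:
    """Orthographic projection of the PTV along the beam axis.

    A BEV pixel belongs to the region iff at least one PTV voxel center
    projects into it.  Contours are extracted at the 0.5 level of the
    padded binary mask (marching squares) and converted to mm.
    """
    if not np.any(ptv_mask):
        raise ValueError("PTV mask is empty")
    if pixel_mm is None:
        pixel_mm = min(grid.spacing_mm)
    flat = np.flatnonzero(np.asarray(ptv_mask, dtype=bool).ravel())
    points = grid.voxel_centers_mm(flat)
    u, v, _ = geometry.bev_coords(points)

    u0 = u.min() - 2 * pixel_mm
    v0 = v.min() - 2 * pixel_mm
    iu = np.rint((u - u0) / pixel_mm).astype(int)
    iv = np.rint((v - v0) / pixel_mm).astype(int)
    mask = np.zeros((iu.max() + 3, iv.max() + 3), dtype=bool)
    mask[iu, iv] = True
    if not mask.any():
        raise ValueError("empty BEV projection")

    contours = []
    for c in measure.find_contours(mask.astype(float), 0.5):
        if len(c) < 3 or not np.allclose(c[0], c[-1]):
            continue  # open fragments touch the (padded, hence unused) border
        contours.append(c * pixel_mm + np.array([u0, v0]))
    return BevRegion(mask, float(pixel_mm), (float(u0), float(v0)), contours)


def cvt_interior_spots(region: BevRegion, spacing_mm: float = 5.0,
                       seed: int = 0, max_iter: int = 50,
                       tol_mm: float = 0.1) -> np.ndarray:
    """Centroidal-Voronoi spot positions inside the region.

    ``k = round(area / spacing**2)`` generators are initialized uniformly
    at random over region pixels (fixed seed) and relaxed with Lloyd
    iterations (assign pixels to the nearest generator, move each generator
    to its cell centroid) until the largest move falls below ``tol_mm`` or
    ``max_iter`` is reached.  Generators are finally snapped into the
    region if a non-convex cell put a centroid outside.

    A region smaller than one ``spacing**2`` cell yields its single
    centroid.
    """
    pix = region.pixel_centers_mm()
    k = int(round(region.area_mm2 / spacing_mm ** 2))
    if k <= 1 or len(pix) == 1:
        return region.pixel_centers_mm().mean(axis=0, keepdims=True)
    k = min(k, len(pix))

    rng = np.random.default_rng(seed)
    gen = pix[rng.choice(len(pix), size=k, replace=False)].astype(float)
    for _ in range(max_iter):
        _, labels = cKDTree(gen).query(pix)
        new = gen.copy()
        counts = np.bincount(labels, minlength=k)
        sums_u = np.bincount(labels, weights=pix[:, 0], minlength=k)
        sums_v = np.bincount(labels, weights=pix[:, 1], minlength=k)
        nonempty = counts > 0
        new[nonempty, 0] = sums_u[nonempty] / counts[nonempty]
        new[nonempty, 1] = sums_v[nonempty] / counts[nonempty]
        move = np.linalg.norm(new - gen, axis=1).max()
        gen = new
        if move < tol_mm:
            break

    outside = ~region.contains_points(gen)
    if np.any(outside):
        _, nearest = cKDTree(pix).query(gen[outside])
        gen[outside] = pix[nearest]
    return gen


def border_spots(region: BevRegion, spacing_mm: float = 5.0) -> np.ndarray:
    """Spots along each closed contour at ~equal arc-length steps.

    Each contour of length ``L`` receives ``n = round(L / spacing)`` points
    at exact steps ``L / n`` (the closure remainder is spread evenly), so
    consecutive arc-length gaps stay within [0.8, 1.2] x spacing.
    """
    points = []
    for contour in region.contours:
        seg = np.linalg.norm(np.diff(contour, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        L = arclen[-1]
        if L < spacing_mm:
            continue
        n = max(1, int(round(L / spacing_mm)))
        targets = np.arange(n) * (L / n)
        pu = np.interp(targets, arclen, contour[:, 0])
        pv = np.interp(targets, arclen, contour[:, 1])
        points.append(np.column_stack([pu, pv]))
    if not points:
        return np.empty((0, 2))
    return np.vstack(points)


def serpentine_order(positions: np.ndarray, row_pitch_mm: float = 5.0) -> np.ndarray:
    """Boustrophedon scan order: group by BEV rows (v), alternate u sweep.

    Returns the index permutation that orders ``positions`` row by row,
    left-to-right on even rows and right-to-left on odd rows.
    """
    positions = np.atleast_2d(positions)
    if len(positions) == 0:
        return np.empty(0, dtype=int)
    v0 = positions[:, 1].min()
    rows = np.rint((positions[:, 1] - v0) / row_pitch_mm).astype(int)
    u = positions[:, 0]
    u_key = np.where(rows % 2 == 0, u, -u)
    return np.lexsort((u_key, rows))
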