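"""Dose-influence matrices and spot-weight/position optimization.

The planning workflow mirrors standard scanned-beam practice: per field,
dose-per-unit-weight columns are precomputed on a regular 2 mm BEV node
grid covering the projected target plus a 2-sigma apron; the column of a
spot at an arbitrary position is the bilinear combination of its four
surrounding node columns.  Nonnegative spot weights are then found by
projected gradient descent with a backtracking (Armijo) line search on a
scorecard of quadratic one-sided penalties, optionally alternated with
local per-spot position refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage, sparse

from .beams import BeamModel, BeamTransport, FieldGeometry
from .grids import StructureSet, VoxelGrid
from .spots import BevRegion, Spot, project_ptv

__all__ = [
    "ColumnSet",
    "DoseInfluenceMatrix",
    "Objective",
    "Scorecard",
    "OptimizationResult",
    "build_influence",
    "interpolate_column",
    "objective_value",
    "optimize_weights",
    "optimize_positions",
    "default_scorecard",
    "conformity_ring",
]

OBJECTIVE_KINDS = ("min_dose", "max_dose", "mean_dose_max", "uniform")


@dataclass
class ColumnSet:
    """A set of dose-per-unit-weight columns over a voxel subset.

    ``matrix`` is (n_rows x n_columns) sparse, Gy/MU; ``rows_index`` maps
    matrix rows to flat voxel indices of ``grid``.
    """

    matrix: sparse.spmatrix
    rows_index: np.ndarray
    grid: VoxelGrid
    field_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = sparse.csc_matrix(self.matrix)
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("influence entries must be >= 0")
        self.rows_index = np.asarray(self.rows_index)
        if self.matrix.shape[0] != len(self.rows_index):
            raise ValueError("rows_index length must match matrix rows")

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[1]

    def dose_rows(self, weights: np.ndarray) -> np.ndarray:
        return np.asarray(self.matrix @ np.asarray(weights, dtype=float)).ravel()

    def dose_grid(self, weights: np.ndarray) -> VoxelGrid:
        """Dose distribution (Gy) for the given weights, zero off-rows."""
        out = np.zeros(self.grid.n_voxels)
        out[self.rows_index] = self.dose_rows(weights)
        return self.grid.like(out.reshape(self.grid.dims))


@dataclass
class DoseInfluenceMatrix(ColumnSet):
    """Node-grid influence: columns live on a regular BEV lattice.

    ``node_u``/``node_v`` are the lattice coordinates (mm, constant pitch)
    and ``node_col[i, j]`` the matrix column of node (i, j), or -1 where a
    lattice point lies outside the apron and carries no column.
    """

    node_u: np.ndarray = field(default_factory=lambda: np.zeros(0))
    node_v: np.ndarray = field(default_factory=lambda: np.zeros(0))
    node_col: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=int))
    pitch_mm: float = 2.0


@dataclass
class Objective:
    """One scorecard objective: a one-sided (or uniform) quadratic penalty.

    ``level_Gy`` may be a per-voxel array for the ``uniform`` kind (used
    e.g. to re-fit a known achievable dose); one-sided kinds take scalars.
    """

    structure: str
    kind: str
    level_Gy: Union[float, np.ndarray]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind '{self.kind}'")
        if self.weight <= 0:
            raise ValueError("objective priority weight must be > 0")
        if np.any(np.asarray(self.level_Gy) < 0):
            raise ValueError("dose levels must be >= 0")


@dataclass
class Scorecard:
    """An ordered list of objectives referencing named structures."""

    objectives: List[Objective] = field(default_factory=list)

    def validate(self, structures: StructureSet) -> None:
        for o in self.objectives:
            if o.structure not in structures:
                raise KeyError(f"objective references unknown structure '{o.structure}'")

    def __iter__(self):
        return iter(self.objectives)

    def __len__(self) -> int:
        return len(self.objectives)

    def scaled(self, factor: float) -> "Scorecard":
        return Scorecard([
            Objective(o.structure, o.kind, o.level_Gy, o.weight * factor)
            for o in self.objectives
        ])


@dataclass
class OptimizationResult:
    weights: np.ndarray
    trace: np.ndarray
    converged: bool
    iterations: int


def conformity_ring(structures: StructureSet, margin_mm: float = 15.0) -> np.ndarray:
    """Shell around the PTV (dilation minus PTV, clipped to BODY).

    Used as a surrogate normal-tissue structure so the optimizer confines
    the high-dose region without carrying every BODY voxel.
    """
    spacing = np.asarray(structures.grid.spacing_mm)
    iters = max(1, int(round(margin_mm / spacing.min())))
    dil = ndimage.binary_dilation(structures.ptv, iterations=iters)
    return dil & ~structures.ptv & structures.body


def default_scorecard(structures: StructureSet, prescription_Gy: float = 30.0,
                      oar_max_fraction: float = 0.67,
                      oar_mean_fraction: float = 0.33) -> Scorecard:
    """Preset scorecard: PTV uniformity and coverage, OAR max/mean caps,
    and a conformity cap on the RING structure (if present).

    The objective lists are surrogates standing in for clinical-protocol
    scorecards; levels are fractions of the prescription and configurable.
    """
    R = prescription_Gy
    objs = [
        Objective("PTV", "uniform", R, 100.0),
        Objective("PTV", "min_dose", 0.95 * R, 100.0),
    ]
    for name in structures.oar_names:
        objs.append(Objective(name, "max_dose", oar_max_fraction * R, 1.0))
        objs.append(Objective(name, "mean_dose_max", oar_mean_fraction * R, 1.0))
    if "RING" in structures:
        objs.append(Objective("RING", "max_dose", 0.6 * R, 5.0))
    return Scorecard(objs)


# ---------------------------------------------------------------------------
# Influence construction and interpolation


def build_influence(density: VoxelGrid, structures: StructureSet,
                    geometry: FieldGeometry, model: BeamModel,
                    spot_grid_pitch_mm: float = 2.0,
                    rows_mask: Optional[np.ndarray] = None,
                    apron_sigmas: float = 2.0,
                    transport: Optional[BeamTransport] = None,
                    region: Optional[BevRegion] = None,
                    truncation_rel: float = 1e-4,
                    dtype=np.float32,
                    field_id: str = "") -> DoseInfluenceMatrix:
    """Precompute per-node dose columns on a regular BEV spot grid.

    Nodes cover the projected PTV plus an apron of ``apron_sigmas`` times
    the entrance core sigma.  Rows default to the union of all structure
    masks.  A shared :class:`BeamTransport` may be passed to reuse cached
    radiological depths.
    """
    if rows_mask is None:
        rows_mask = np.zeros(density.dims, dtype=bool)
        for name in structures:
            rows_mask |= structures[name]
    rows_index = np.flatnonzero(np.asarray(rows_mask, dtype=bool).ravel())
    if transport is None:
        transport = BeamTransport(density, geometry, rows_index)
    elif not np.array_equal(transport.flat_index, rows_index):
        raise ValueError("supplied transport covers a different voxel set")

    if region is None:
        region = project_ptv(structures.ptv, density, geometry)
    apron = apron_sigmas * model.lateral.sigma1_mm
    pix = region.pixel_centers_mm()
    u_lo, v_lo = pix.min(axis=0) - apron
    u_hi, v_hi = pix.max(axis=0) + apron
    p = float(spot_grid_pitch_mm)
    node_u = u_lo + p * np.arange(int(np.floor((u_hi - u_lo) / p)) + 1)
    node_v = v_lo + p * np.arange(int(np.floor((v_hi - v_lo) / p)) + 1)
    if len(node_u) == 0 or len(node_v) == 0:
        raise ValueError("empty BEV region: no spot-grid nodes")

    # Keep nodes within the apron distance of the region.
    dist = ndimage.distance_transform_edt(~region.mask, sampling=region.pixel_mm)
    uu, vv = np.meshgrid(node_u, node_v, indexing="ij")
    ij = np.rint(
        (np.column_stack([uu.ravel(), vv.ravel()]) - np.asarray(region.origin_uv_mm))
        / region.pixel_mm
    ).astype(int)
    ij = np.clip(ij, 0, np.asarray(region.mask.shape) - 1)
    keep = (dist[ij[:, 0], ij[:, 1]] <= apron).reshape(uu.shape)

    node_col = np.full(uu.shape, -1, dtype=int)
    indptr = [0]
    indices: List[np.ndarray] = []
    data: List[np.ndarray] = []
    col = 0
    for i in range(uu.shape[0]):
        for j in range(uu.shape[1]):
            if not keep[i, j]:
                continue
            local, vals = transport.column(
                model, (node_u[i], node_v[j]), truncation_rel, dtype=dtype
            )
            indices.append(local.astype(np.int32))
            data.append(vals)
            indptr.append(indptr[-1] + len(local))
            node_col[i, j] = col
            col += 1
    if col == 0:
        raise ValueError("no spot-grid nodes within the apron")
    matrix = sparse.csc_matrix(
        (np.concatenate(data), np.concatenate(indices), np.array(indptr)),
        shape=(len(rows_index), col),
    )
    return DoseInfluenceMatrix(
        matrix=matrix, rows_index=rows_index, grid=density, field_id=field_id,
        node_u=node_u, node_v=node_v, node_col=node_col, pitch_mm=p,
    )


def interpolate_column(M: DoseInfluenceMatrix, position_bev_mm: Sequence[float]):
    """Bilinear combination of the 4 node columns surrounding a position.

    At a node the node's column is returned exactly.  Positions outside
    the node hull (or whose surrounding nodes carry no column) raise.
    """
    x, y = float(position_bev_mm[0]), float(position_bev_mm[1])
    p = M.pitch_mm
    fx = (x - M.node_u[0]) / p
    fy = (y - M.node_v[0]) / p
    eps = 1e-9
    if fx < -eps or fy < -eps or fx > len(M.node_u) - 1 + eps or fy > len(M.node_v) - 1 + eps:
        raise ValueError(f"position ({x}, {y}) outside the spot-grid node hull")
    i0 = min(int(np.floor(fx + eps)), len(M.node_u) - 1)
    j0 = min(int(np.floor(fy + eps)), len(M.node_v) - 1)
    tx = fx - i0
    ty = fy - j0
    i1 = min(i0 + 1, len(M.node_u) - 1)
    j1 = min(j0 + 1, len(M.node_v) - 1)

    out = None
    for (i, j, w) in (
        (i0, j0, (1 - tx) * (1 - ty)),
        (i1, j0, tx * (1 - ty)),
        (i0, j1, (1 - tx) * ty),
        (i1, j1, tx * ty),
    ):
        if w <= 1e-12:
            continue
        c = M.node_col[i, j]
        if c < 0:
            raise ValueError(
                f"position ({x}, {y}) needs node ({i}, {j}) which carries no column"
            )
        term = M.matrix[:, c] * w
        out = term if out is None else out + term
    return sparse.csc_matrix(out)


# ---------------------------------------------------------------------------
# Objective and solvers


def _objective_rows(scorecard: Scorecard, structures: StructureSet,
                    rows_index: np.ndarray):
    """Map each objective's structure mask onto matrix-row positions."""
    scorecard.validate(structures)
    pos = np.full(structures.grid.n_voxels, -1, dtype=np.int64)
    pos[rows_index] = np.arange(len(rows_index))
    objs = []
    for o in scorecard:
        flat = np.flatnonzero(structures[o.structure].ravel())
        rows = pos[flat]
        if np.any(rows < 0):
            raise ValueError(
                f"structure '{o.structure}' has voxels outside the influence rows"
            )
        level = np.asarray(o.level_Gy, dtype=float)
        if level.ndim > 0 and level.size not in (1, len(rows)):
            raise ValueError("per-voxel objective level length mismatch")
        objs.append((o, rows, level))
    return objs


def _value_and_residual(d: np.ndarray, objs) -> Tuple[float, np.ndarray]:
    """Objective value and its gradient w.r.t. per-row dose."""
    f = 0.0
    resid = np.zeros_like(d)
    for o, rows, level in objs:
        dv = d[rows]
        n = len(rows)
        if o.kind == "min_dose":
            v = np.maximum(level - dv, 0.0)
            f += o.weight * np.mean(v ** 2)
            resid[rows] += (-2.0 * o.weight / n) * v
        elif o.kind == "max_dose":
            v = np.maximum(dv - level, 0.0)
            f += o.weight * np.mean(v ** 2)
            resid[rows] += (2.0 * o.weight / n) * v
        elif o.kind == "mean_dose_max":
            v = max(float(dv.mean() - level), 0.0)
            f += o.weight * v ** 2
            resid[rows] += (2.0 * o.weight * v) / n
        else:  # uniform
            v = dv - level
            f += o.weight * np.mean(v ** 2)
            resid[rows] += (2.0 * o.weight / n) * v
    return f, resid


def objective_value(dose: Union[VoxelGrid, np.ndarray], scorecard: Scorecard,
                    structures: StructureSet) -> float:
    """Scorecard penalty of a dose distribution (0 iff all objectives met)."""
    values = dose.values if isinstance(dose, VoxelGrid) else np.asarray(dose)
    if values.shape != structures.grid.dims:
        raise ValueError("dose grid incongruent with structure masks")
    rows_index = np.arange(values.size)
    objs = _objective_rows(scorecard, structures, rows_index)
    f, _ = _value_and_residual(values.ravel().astype(float), objs)
    return float(f)


def _stack(columns: Union[ColumnSet, Sequence[ColumnSet]]):
    sets = [columns] if isinstance(columns, ColumnSet) else list(columns)
    rows_index = sets[0].rows_index
    for s in sets[1:]:
        if not np.array_equal(s.rows_index, rows_index):
            raise ValueError("all fields must share the same influence rows")
    splits = np.cumsum([s.n_spots for s in sets])[:-1]
    mat = sparse.hstack([s.matrix for s in sets], format="csr")
    # Densify moderate-size systems: BLAS matvecs dominate solver time.
    if mat.shape[0] * mat.shape[1] * 4 < 6e8:
        mat = np.asarray(mat.todense(), dtype=np.float32)
    return sets, mat, splits, rows_index


def _init_weights(n: int, mat, objs) -> np.ndarray:
    """Uniform weights scaled so the first uniform/min-dose structure's
    mean dose matches its level (deterministic warm start)."""
    w = np.ones(n)
    for o, rows, level in objs:
        if o.kind in ("uniform", "min_dose"):
            d = np.asarray(mat @ w).ravel()
            mean = float(d[rows].mean())
            target = float(np.mean(level))
            if mean > 0 and target > 0:
                w *= target / mean
            break
    return w


def optimize_weights(columns: Union[ColumnSet, Sequence[ColumnSet]],
                     scorecard: Scorecard, structures: StructureSet,
                     init: Optional[np.ndarray] = None,
                     tol: float = 1e-6, max_iter: int = 500) -> OptimizationResult:
    """Minimize the scorecard penalty over nonnegative spot weights.

    Projected gradient descent with backtracking line search on
    ``f(w) = objective(sum_fields M_f w_f)`` subject to ``w >= 0``.  The
    objective trace is non-increasing by construction; iteration stops on
    relative change below ``tol`` or ``max_iter``.
    """
    sets, mat, splits, rows_index = _stack(columns)
    n = sum(s.n_spots for s in sets)
    if n == 0:
        raise ValueError("no spots to optimize")
    mmax = mat.max() if not sparse.issparse(mat) else (mat.data.max() if mat.nnz else 0.0)
    if mmax <= 0:
        raise ValueError("all-zero influence matrix")

    objs = _objective_rows(scorecard, structures, rows_index)

    if init is not None:
        w = np.asarray(init, dtype=float).copy()
        if len(w) != n or np.any(w < 0):
            raise ValueError("init weights must be nonnegative, one per spot")
    else:
        w = _init_weights(n, mat, objs)

    if len(scorecard) == 0:
        return OptimizationResult(w, np.array([0.0]), True, 0)

    def matvec(x):
        return np.asarray(mat @ x).ravel().astype(float)

    def rmatvec(r):
        return np.asarray(mat.T @ r.astype(mat.dtype)).ravel().astype(float)

    d = matvec(w)
    f, resid = _value_and_residual(d, objs)
    trace = [f]
    alpha = 1.0 / max(mmax, 1e-12) ** 2
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = rmatvec(resid)
        # Backtracking with projection; grow the step again on success.
        alpha *= 2.0
        for _ in range(60):
            w_new = np.maximum(w - alpha * g, 0.0)
            d_new = matvec(w_new)
            f_new, resid_new = _value_and_residual(d_new, objs)
            decrease = float(g @ (w - w_new))
            if f_new <= f - 1e-4 * decrease + 1e-30:
                break
            alpha *= 0.5
        else:
            trace.append(f)
            converged = True
            break
        if f_new > f:  # numerical guard: never let the trace increase
            trace.append(f)
            converged = True
            break
        rel = (f - f_new) / max(f, 1e-30)
        w, d, f, resid = w_new, d_new, f_new, resid_new
        trace.append(f)
        if rel < tol or f == 0.0:
            converged = True
            break
    return OptimizationResult(w, np.asarray(trace), converged, it)


def split_weights(result_weights: np.ndarray,
                  columns: Sequence[ColumnSet]) -> List[np.ndarray]:
    """Split a concatenated weight vector back into per-field vectors."""
    splits = np.cumsum([c.n_spots for c in columns])[:-1]
    return np.split(np.asarray(result_weights), splits)


def optimize_positions(spots: List[List[Spot]],
                       influences: Sequence[DoseInfluenceMatrix],
                       scorecard: Scorecard, structures: StructureSet,
                       weights: Optional[np.ndarray] = None,
                       rounds: int = 3, fd_step_mm: float = 0.5,
                       tol: float = 1e-6, max_iter: int = 200):
    """Alternate local spot-position refinement with weight re-fitting.

    Each round proposes, per spot, a finite-difference gradient step on the
    interpolated node columns (bounded by half the node pitch) and accepts
    it only if the re-fit objective improves; ties keep the original
    position.  Returns ``(spots, weights, objective_trace_per_round)``.
    """
    def columns_for(all_spots):
        sets = []
        for f, M in enumerate(influences):
            cols = [interpolate_column(M, (s.bev_x_mm, s.bev_y_mm)) for s in all_spots[f]]
            sets.append(ColumnSet(sparse.hstack(cols, format="csc"),
                                  M.rows_index, M.grid, M.field_id))
        return sets

    accepted = [list(fs) for fs in spots]
    sets = columns_for(accepted)
    res = optimize_weights(sets, scorecard, structures, init=weights,
                           tol=tol, max_iter=max_iter)
    best_f = res.trace[-1]
    trace = [best_f]
    for _ in range(rounds):
        spots = [list(fs) for fs in accepted]
        objs = _objective_rows(scorecard, structures, influences[0].rows_index)
        w_fields = split_weights(res.weights, sets)
        d = np.zeros(len(influences[0].rows_index))
        for s_set, wf in zip(sets, w_fields):
            d += s_set.dose_rows(wf)
        _, resid = _value_and_residual(d, objs)
        for f, M in enumerate(influences):
            half = M.pitch_mm / 2.0
            for k, s in enumerate(spots[f]):
                wk = w_fields[f][k]
                if wk <= 0:
                    continue
                pos = np.array([s.bev_x_mm, s.bev_y_mm])
                grad = np.zeros(2)
                try:
                    base = interpolate_column(M, pos)
                    for a in range(2):
                        dpos = pos.copy()
                        dpos[a] += fd_step_mm
                        dcol = interpolate_column(M, dpos)
                        diff = np.asarray((dcol - base).todense()).ravel()
                        grad[a] = wk * float(resid @ diff) / fd_step_mm
                except ValueError:
                    continue
                norm = np.linalg.norm(grad)
                if norm == 0:
                    continue
                cand = pos - half * grad / norm  # step bounded by half pitch
                try:
                    interpolate_column(M, cand)
                except ValueError:
                    continue
                spots[f][k] = Spot(float(cand[0]), float(cand[1]), s.weight, s.field_id)
        new_sets = columns_for(spots)
        new_res = optimize_weights(new_sets, scorecard, structures,
                                   init=res.weights, tol=tol, max_iter=max_iter)
        if new_res.trace[-1] < best_f:
            accepted, sets, res, best_f = spots, new_sets, new_res, new_res.trace[-1]
        # a worsening proposal round is discarded wholesale (tie keeps original)
        trace.append(best_f)
    return accepted, res.weights, np.asarray(trace)
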