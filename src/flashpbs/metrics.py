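"""Plan evaluation: DVH/DRDVH curves, dose quantiles, HI/CI, FLASH index.

The FLASH index of a structure,

    FI(X Gy, Y Gy/s) = VolDRDVH(X, Y) / VolDVH(X),

is the fraction of the structure's voxels receiving dose > X Gy at a PBS
dose rate >= Y Gy/s, divided by the fraction receiving dose > X Gy.  It is
a model-independent plan metric: it quantifies how much of the relevant
high-dose volume meets ultra-high-dose-rate conditions without assuming
any magnitude for the radiobiological FLASH effect.  FI = 1 means every
voxel above the dose threshold was UHDR-delivered; FI is defined as
exactly 0 when no voxel exceeds the dose threshold.

Convention throughout: strict ``>`` for dose thresholds, ``>=`` for
dose-rate thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .delivery import DoseRateConfig, flash_dose_map
from .grids import StructureSet, VoxelGrid

__all__ = [
    "CumulativeVolumeCurve",
    "FlashIndexResult",
    "dvh",
    "drdvh",
    "dose_quantile",
    "plan_metrics",
    "flash_index",
    "fi_robustness_scan",
]


@dataclass
class CumulativeVolumeCurve:
    """Fraction of a structure's volume above each dose level."""

    levels_Gy: np.ndarray
    volume_fraction: np.ndarray
    structure: str = ""
    kind: str = "DVH"            # "DVH" | "DRDVH"

    def __post_init__(self) -> None:
        self.levels_Gy = np.asarray(self.levels_Gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if np.any(np.diff(self.levels_Gy) <= 0):
            raise ValueError("dose levels must be strictly increasing")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative volume curve must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "structure": self.structure,
            "kind": self.kind,
            "dose_Gy": self.levels_Gy,
            "volume_fraction": self.volume_fraction,
        })


@dataclass
class FlashIndexResult:
    """FI with its thresholds and the two volume fractions of its ratio."""

    structure: str
    dose_threshold_Gy: float
    dr_threshold_Gy_per_s: float
    vol_dvh: float
    vol_drdvh: float
    fi: float


def _mask_doses(dose: VoxelGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.dims:
        raise ValueError("mask incongruent with dose grid")
    if not mask.any():
        raise ValueError("empty structure mask")
    return dose.values[mask]


def dvh(dose: VoxelGrid, mask: np.ndarray,
        levels_Gy: Sequence[float], structure: str = "",
        kind: str = "DVH") -> CumulativeVolumeCurve:
    """Cumulative DVH: fraction of mask voxels with dose strictly above
    each level (strict ``>`` to match the FLASH-index convention)."""
    d = _mask_doses(dose, mask)
    levels = np.asarray(levels_Gy, dtype=float)
    frac = np.array([(d > L).mean() for L in levels])
    return CumulativeVolumeCurve(levels, frac, structure, kind)


def drdvh(flash_dose: VoxelGrid, mask: np.ndarray,
          levels_Gy: Sequence[float], structure: str = "") -> CumulativeVolumeCurve:
    """DVH of the UHDR-delivered dose map (the DRDVH of the plan)."""
    return dvh(flash_dose, mask, levels_Gy, structure, kind="DRDVH")


def dose_quantile(dose: VoxelGrid, mask: np.ndarray, x_percent: float) -> float:
    """Dx%: minimum dose received by the hottest x% of the structure.

    Voxel doses are sorted descending and linearly interpolated at
    midpoint plotting positions ((i + 0.5)/N), clamped at the extremes.
    """
    if not (0.0 < x_percent < 100.0):
        raise ValueError("x_percent must be in (0, 100)")
    d = np.sort(_mask_doses(dose, mask))[::-1]
    n = len(d)
    positions = (np.arange(n) + 0.5) / n
    return float(np.interp(x_percent / 100.0, positions, d))


def _volume_above(values: np.ndarray, level: float, strict: bool) -> int:
    return int((values > level).sum() if strict else (values >= level).sum())


def plan_metrics(dose: VoxelGrid, structures: StructureSet,
                 prescription_Gy: float,
                 reference_dose_Gy: float = 10.0) -> pd.DataFrame:
    """Per-structure metric table.

    All structures: D2%, D95%, D98%, Dmean (Gy) and V>10Gy (%).  PTV rows
    additionally report HI98 = D98/D2 and the conformity indices
    CI_X = (PTV volume >= X% of prescription) / (BODY volume >= X%), for
    X = 95 and 50; a CI is reported as NaN when no voxel reaches the
    isodose.
    """
    rows = []
    body_vals = dose.values[structures.body]
    ptv_vals = dose.values[structures.ptv]
    for name in structures:
        vals = _mask_doses(dose, structures[name])
        row = {
            "structure": name,
            "D2_Gy": dose_quantile(dose, structures[name], 2.0),
            "D95_Gy": dose_quantile(dose, structures[name], 95.0),
            "D98_Gy": dose_quantile(dose, structures[name], 98.0),
            "Dmean_Gy": float(vals.mean()),
            "V_gt_10Gy_pct": 100.0 * float((vals > reference_dose_Gy).mean()),
            "HI98": np.nan, "CI95": np.nan, "CI50": np.nan,
        }
        if name == "PTV":
            row["HI98"] = row["D98_Gy"] / row["D2_Gy"] if row["D2_Gy"] > 0 else np.nan
            for x, key in ((95.0, "CI95"), (50.0, "CI50")):
                level = x / 100.0 * prescription_Gy
                vtot = _volume_above(body_vals, level, strict=False)
                vptv = _volume_above(ptv_vals, level, strict=False)
                row[key] = vptv / vtot if vtot > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("structure")


def flash_index(dose: VoxelGrid, flash_dose: VoxelGrid, mask: np.ndarray,
                dose_threshold_Gy: float = 10.0,
                dr_threshold_Gy_per_s: float = 40.0,
                structure: str = "") -> FlashIndexResult:
    """FLASH index FI(X, Y) of a structure.

    ``flash_dose`` must already encode the dose-rate condition (dose
    delivered at PBS dose rate >= Y); the threshold is carried through for
    reporting.  FI = 0 when VolDVH = 0.
    """
    dose.require_congruent(flash_dose)
    d = _mask_doses(dose, mask)
    f = flash_dose.values[np.asarray(mask, dtype=bool)]
    vol_dvh = float((d > dose_threshold_Gy).mean())
    vol_drdvh = float((f > dose_threshold_Gy).mean())
    fi = vol_drdvh / vol_dvh if vol_dvh > 0 else 0.0
    return FlashIndexResult(structure, float(dose_threshold_Gy),
                            float(dr_threshold_Gy_per_s), vol_dvh, vol_drdvh, fi)


def fi_robustness_scan(total_dose: VoxelGrid,
                       field_doses: Sequence[VoxelGrid],
                       field_dose_rates: Sequence[VoxelGrid],
                       mask: np.ndarray,
                       dose_thresholds_Gy: Sequence[float] = (0, 5, 10, 15, 20),
                       dr_thresholds_Gy_per_s: Sequence[float] = (30, 40, 60, 80, 100),
                       cfg: Optional[DoseRateConfig] = None,
                       structure: str = "") -> pd.DataFrame:
    """Full factorial FI table over dose and dose-rate thresholds.

    The UHDR dose map is recomputed per dose-rate threshold, so for a
    fixed dose threshold FI is non-increasing in the dose-rate threshold.
    """
    cfg = cfg or DoseRateConfig()
    rows = []
    for dr_thr in dr_thresholds_Gy_per_s:
        fmap = flash_dose_map(field_doses, field_dose_rates, cfg,
                              uhdr_threshold_Gy_per_s=dr_thr)
        for d_thr in dose_thresholds_Gy:
            r = flash_index(total_dose, fmap, mask, d_thr, dr_thr, structure)
            rows.append({
                "structure": structure,
                "dose_thr_Gy": float(d_thr),
                "dr_thr_Gy_per_s": float(dr_thr),
                "VolDVH": r.vol_dvh,
                "VolDRDVH": r.vol_drdvh,
                "FI": r.fi,
            })
    return pd.DataFrame(rows)
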