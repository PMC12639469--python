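"""File formats and run manifests.

Volumetric data are NIfTI (via :mod:`flashpbs.grids`); tabular outputs are
CSV; configurations, plans and manifests are JSON.  Every pipeline run
writes a manifest (config hash, seed, package/library versions) sufficient
to reproduce its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .delivery import DeliveryTimeline
from .grids import StructureSet, VoxelGrid, read_grid, write_grid
from .phantom import DensityInsert, OarSpec, PhantomSpec
from .spots import Spot

__all__ = [
    "read_grid", "write_grid",
    "save_phantom", "load_phantom_spec",
    "save_plan_spots", "load_plan_spots",
    "save_timeline_csv", "write_manifest",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def save_phantom(density: VoxelGrid, structures: StructureSet,
                 spec: PhantomSpec, out_dir: Union[str, Path]) -> Path:
    """Write density + one NIfTI per mask + a JSON sidecar with the spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_grid(density, out / "density.nii.gz")
    for name in structures:
        write_grid(density.like(structures[name].astype(np.float64)),
                   out / f"mask_{name}.nii.gz")
    sidecar = {"spec": _jsonable(spec), "seed": spec.seed}
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_phantom_spec(path: Union[str, Path]) -> PhantomSpec:
    """Rebuild a PhantomSpec from a phantom.json sidecar or bare spec JSON."""
    raw = json.loads(Path(path).read_text())
    data = raw.get("spec", raw)
    data = dict(data)
    data["oars"] = [OarSpec(**{**o, "size_mm": tuple(o["size_mm"]),
                               "offset_mm": tuple(o["offset_mm"])})
                    for o in data.get("oars", [])]
    data["inserts"] = [DensityInsert(center_mm=tuple(i["center_mm"]),
                                     semi_axes_mm=tuple(i["semi_axes_mm"]),
                                     density=i["density"])
                       for i in data.get("inserts", [])]
    for key in ("dims", "spacing_mm", "target_center_mm", "field_angles_deg"):
        if key in data:
            data[key] = tuple(data[key])
    return PhantomSpec(**data)


def save_plan_spots(fields: Dict[str, List[Spot]], particle: str,
                    energy_MeV: float, path: Union[str, Path]) -> None:
    """Serialize spots per field: particle, energy, list of (x, y, weight)."""
    doc = {
        "particle": particle,
        "energy_MeV": energy_MeV,
        "fields": {
            fid: [[s.bev_x_mm, s.bev_y_mm, s.weight] for s in spots]
            for fid, spots in fields.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_plan_spots(path: Union[str, Path]):
    doc = json.loads(Path(path).read_text())
    fields = {
        fid: [Spot(x, y, w, fid) for x, y, w in spots]
        for fid, spots in doc["fields"].items()
    }
    return fields, doc["particle"], doc["energy_MeV"]


def save_timeline_csv(timeline: DeliveryTimeline, path: Union[str, Path]) -> None:
    lines = ["spot_id,start_s,duration_s,weight_MU"]
    for i in range(timeline.n_emissions):
        lines.append(f"{timeline.spot_index[i]},{timeline.start_s[i]:.9g},"
                     f"{timeline.duration_s[i]:.9g},{timeline.weight_MU[i]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(out_dir: Union[str, Path], config: dict, seed: int) -> Path:
    """Run manifest: canonical config hash, seed and versions."""
    import nibabel
    import pandas
    import scipy

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(_jsonable(config), sort_keys=True)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": int(seed),
        "versions": {
            "flashpbs": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
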