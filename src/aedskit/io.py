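"""Text round-tripping for trajectories, parameters, systems and traces.

Formats (all UTF-8, units kJ·mol⁻¹ / degrees / kelvin):

* energy trajectories — TSV with header
  ``# time H_<id>... H_R H_star dV V_restr [x_<coord>...]``; floats are
  written with 17 significant digits so write∘read is bit-exact.
* search traces — TSV with header ``# step E_max E_min offset_<id>...``.
* toy systems and acceleration parameters — YAML mappings with strict
  schema validation (unknown keys are rejected by name).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .dynamics import EnergyTrajectory
from .hamiltonian import AccelerationParams, OffsetVector
from .search import SearchTrace
from .toys import ToySystem

__all__ = [
    "write_energy_trajectory",
    "read_energy_trajectory",
    "write_search_trace",
    "write_system",
    "read_system",
    "write_params",
    "read_params",
]

_F = "%.17g"


def write_energy_trajectory(traj: EnergyTrajectory, path: str | Path) -> None:
    cols = (
        ["time"]
        + [f"H_{i}" for i in traj.ids]
        + ["H_R", "H_star", "dV", "V_restr"]
        + [f"x_{c}" for c in traj.coord_names if traj.coords is not None]
    )
    data = [traj.time] + [traj.h[:, k] for k in range(len(traj.ids))]
    data += [traj.h_r, traj.h_star, traj.dv, traj.v_restr]
    if traj.coords is not None:
        data += [traj.coords[:, j] for j in range(traj.coords.shape[1])]
    mat = np.column_stack(data)
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(cols) + "\n")
        for row in mat:
            fh.write("\t".join(_F % v for v in row) + "\n")


def read_energy_trajectory(path: str | Path) -> EnergyTrajectory:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError(f"{path}:1: expected '# '-prefixed header line")
        cols = header[2:].rstrip("\n").split("\t")
        ids = tuple(c[2:] for c in cols if c.startswith("H_") and c not in ("H_R", "H_star"))
        coord_names = tuple(c[2:] for c in cols if c.startswith("x_"))
        required = ["time"] + [f"H_{i}" for i in ids] + ["H_R", "H_star", "dV", "V_restr"]
        missing = [c for c in required if c not in cols]
        if missing:
            raise ValueError(f"{path}:1: header missing columns {missing}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(cols)} fields, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    mat = np.asarray(rows, dtype=float).reshape(len(rows), len(cols))
    col = {c: mat[:, k] for k, c in enumerate(cols)}
    h = np.column_stack([col[f"H_{i}"] for i in ids]) if len(rows) else np.empty((0, len(ids)))
    coords = np.column_stack([col[f"x_{c}"] for c in coord_names]) if coord_names and len(rows) else None
    return EnergyTrajectory(
        ids=ids,
        time=col["time"] if len(rows) else np.empty(0),
        h=h,
        h_r=col["H_R"] if len(rows) else np.empty(0),
        h_star=col["H_star"] if len(rows) else np.empty(0),
        v_restr=col["V_restr"] if len(rows) else np.empty(0),
        coords=coords,
        coord_names=coord_names,
    )


def write_search_trace(trace: SearchTrace, path: str | Path) -> None:
    cols = ["step", "E_max", "E_min"] + [f"offset_{i}" for i in trace.ids]
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(cols) + "\n")
        for k in range(len(trace.steps)):
            row = [float(trace.steps[k]), trace.e_max[k], trace.e_min[k], *trace.offsets[k]]
            fh.write("\t".join(_F % v for v in row) + "\n")


def write_system(system: ToySystem, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system.to_dict(), fh, sort_keys=False)


def read_system(path: str | Path) -> ToySystem:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ToySystem.from_dict(d)


def write_params(params: AccelerationParams, path: str | Path) -> None:
    d = {
        "e_min": float(params.e_min),
        "e_max": float(params.e_max),
        "anchor": params.offsets.anchor,
        "offsets": {i: float(v) for i, v in zip(params.offsets.ids, params.offsets.values)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_params(path: str | Path) -> AccelerationParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    allowed = {"e_min", "e_max", "anchor", "offsets"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys: {sorted(unknown)}")
    ids = tuple(d["offsets"])
    values = np.array([d["offsets"][i] for i in ids], dtype=float)
    off = OffsetVector.from_values(ids, values, d.get("anchor", ids[0]))
    return AccelerationParams(float(d["e_min"]), float(d["e_max"]), off)
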