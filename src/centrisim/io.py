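"""File export: VTK legacy, CSV, JSON reports and run manifests.

All writers emit plain text.  The VTK legacy ASCII writer covers the two
shapes this package produces: cell-centered fields on the structured
masked mesh (as an unstructured quad grid) and particle trajectories (as
polylines).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Mesh

__all__ = [
    "RunManifest",
    "write_vtk_mesh",
    "write_vtk_trajectories",
    "write_flow_vtk",
    "write_concentration_vtk",
    "write_trajectories_csv",
    "write_json",
    "sha256_of",
]


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one run: config snapshot, software version,
    timestamps, seed, per-stage status and per-file checksums."""

    config: dict
    seed: int | None = None
    version: str = __version__
    started: str = dc_field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    finished: str | None = None
    stages: dict = dc_field(default_factory=dict)
    files: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)

    def record_stage(self, name: str, status: str, **info) -> None:
        self.stages[name] = {"status": status, **info}

    def record_file(self, path: Path) -> None:
        self.files[str(path)] = sha256_of(path)

    def finalize(self, directory: Path) -> Path:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        cfg_hash = hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()
        payload = {
            "software": f"centrisim {self.version}",
            "config": self.config,
            "config_sha256": cfg_hash,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "stages": self.stages,
            "files": self.files,
            "warnings": self.warnings,
        }
        out = Path(directory) / "manifest.json"
        out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return out

    def verify(self) -> bool:
        return all(
            Path(p).exists() and sha256_of(p) == h for p, h in self.files.items()
        )


# -- VTK legacy ASCII ------------------------------------------------------


def write_vtk_mesh(
    path, mesh: Mesh, cell_data: dict[str, np.ndarray] | None = None
) -> Path:
    """Write the fluid cells as a VTK legacy unstructured quad grid.

    ``cell_data`` values are either full (ny, nx) grids (masked entries
    ignored) or flat arrays over fluid cells; vectors have a trailing
    dimension of 2 (padded to 3).
    """
    path = Path(path)
    pts, quads = mesh._nodes_cells()
    n_fluid = mesh.n_cells
    lines = [
        "# vtk DataFile Version 3.0",
        "centrisim field export",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} float",
    ]
    lines += [f"{x:.9g} {y:.9g} 0" for x, y in pts]
    lines.append(f"CELLS {len(quads)} {len(quads) * 5}")
    lines += ["4 " + " ".join(map(str, q)) for q in quads]
    lines.append(f"CELL_TYPES {len(quads)}")
    lines += ["9"] * len(quads)  # VTK_QUAD
    if cell_data:
        lines.append(f"CELL_DATA {n_fluid}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim >= 2 and arr.shape[:2] == (mesh.ny, mesh.nx):
                arr = arr[mesh.fluid]
            if arr.ndim == 2 and arr.shape[1] in (2, 3):
                lines.append(f"VECTORS {name} float")
                for row in arr:
                    z = row[2] if len(row) > 2 else 0.0
                    lines.append(f"{row[0]:.9g} {row[1]:.9g} {z:.9g}")
            else:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in np.ravel(arr)]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_vtk_trajectories(path, history: list[np.ndarray]) -> Path:
    """Write particle trajectories as VTK polylines (z is the depth
    coordinate of the quasi-3D tracker)."""
    path = Path(path)
    all_pts: list[np.ndarray] = []
    offsets: list[tuple[int, int]] = []
    start = 0
    for hist in history:
        xyz = hist[:, 1:4]
        all_pts.append(xyz)
        offsets.append((start, len(xyz)))
        start += len(xyz)
    pts = np.vstack(all_pts) if all_pts else np.zeros((0, 3))
    lines = [
        "# vtk DataFile Version 3.0",
        "centrisim particle trajectories",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} float",
    ]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in pts]
    total = sum(n + 1 for _, n in offsets)
    lines.append(f"LINES {len(offsets)} {total}")
    for s, n in offsets:
        lines.append(str(n) + " " + " ".join(str(s + k) for k in range(n)))
    path.write_text("\n".join(lines) + "\n")
    return path


def _cell_average_velocity(field) -> np.ndarray:
    u_c = 0.5 * (field.u[:, :-1] + field.u[:, 1:])
    v_c = 0.5 * (field.v[:-1, :] + field.v[1:, :])
    vec = np.stack([u_c[field.mesh.fluid], v_c[field.mesh.fluid]], axis=1)
    return vec


def write_flow_vtk(path, field) -> Path:
    """FlowField export: cell-centered velocity vectors and pressure."""
    return write_vtk_mesh(
        path,
        field.mesh,
        cell_data={
            "velocity": _cell_average_velocity(field),
            "pressure": field.p,
            "speed": np.hypot(
                0.5 * (field.u[:, :-1] + field.u[:, 1:]),
                0.5 * (field.v[:-1, :] + field.v[1:, :]),
            ),
        },
    )


def write_concentration_vtk(path, conc) -> Path:
    return write_vtk_mesh(
        path,
        conc.mesh,
        cell_data={
            "concentration": np.where(np.isnan(conc.c), 0.0, conc.c),
            "velocity": _cell_average_velocity(conc.flow),
        },
    )


# -- tabular / JSON --------------------------------------------------------


def write_trajectories_csv(path, result) -> Path:
    path = Path(path)
    pd.DataFrame(result.to_records()).to_csv(path, index=False)
    return path


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
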