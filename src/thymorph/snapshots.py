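"""Snapshot I/O: a JSON mesh dialect for tests and round trips, and an
ASCII legacy-VTK polydata writer for visualisation (cells as polygons
with per-cell scalars: type, age, polarity magnitude, VEGF)."""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .boundaries import EndoBoundary
from .mesh import CellType, Mesh

__all__ = [
    "write_snapshot_json",
    "read_snapshot_json",
    "write_vtk",
]


def write_snapshot_json(
    path,
    mesh: Mesh,
    boundaries: Optional[Sequence[EndoBoundary]] = None,
    field=None,
) -> None:
    d = mesh.to_dict()
    if boundaries:
        d["endo_boundaries"] = [b.to_dict() for b in boundaries]
    if field is not None:
        d["vegf"] = {str(k): v for k, v in field.concentration.items()}
    with open(path, "w") as fh:
        json.dump(d, fh)


def read_snapshot_json(path):
    """Returns ``(mesh, boundaries)``."""
    with open(path) as fh:
        d = json.load(fh)
    mesh = Mesh.from_dict(d)
    boundaries = [
        EndoBoundary.from_dict(b) for b in d.get("endo_boundaries", [])
    ]
    return mesh, boundaries


_TYPE_CODE = {t: i for i, t in enumerate(CellType)}


def write_vtk(path, mesh: Mesh, field=None) -> None:
    """ASCII legacy VTK polydata: one polygon per cell, per-cell scalars."""
    vids = sorted(np.flatnonzero(mesh.alive_mask).tolist())
    remap = {v: i for i, v in enumerate(vids)}
    cells = [mesh.cells[c] for c in sorted(mesh.cells)]
    lines: List[str] = [
        "# vtk DataFile Version 3.0",
        "thymorph tissue snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vids)} float",
    ]
    for v in vids:
        x, y = mesh.positions[v]
        lines.append(f"{x:.9g} {y:.9g} 0")
    size = sum(len(c.ring) + 1 for c in cells)
    lines.append(f"POLYGONS {len(cells)} {size}")
    for c in cells:
        lines.append(
            f"{len(c.ring)} " + " ".join(str(remap[v]) for v in c.ring)
        )
    lines.append(f"CELL_DATA {len(cells)}")

    def scalar(name, values, fmt="{:.9g}"):
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(fmt.format(v) for v in values)

    scalar("cell_type", [_TYPE_CODE[c.type] for c in cells], "{}")
    scalar("age", [c.state.age for c in cells])
    scalar(
        "polarity_magnitude",
        [float(np.linalg.norm(c.state.polarity)) for c in cells],
    )
    if field is not None:
        scalar(
            "vegf",
            [field.concentration.get(c.id, 0.0) for c in cells],
        )
    Path(path).write_text("\n".join(lines) + "\n")
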