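"""Endothelial boundary conditions (endo-BC).

Blood vessels inside the simulated cross-section connect to larger
vessels that lie outside it. Two devices stand in for those unseen
connections: (i) the boundary vertices of peripheral stalk cells are
fixed in place, and (ii) from the founding stalk cell of every branch,
two parallel semi-infinite lines extend outward, forming a corridor
that epithelial vertices may not enter. Epithelial growth then flows
around the corridors, so two separated buds can never fuse over a
nascent vessel.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .mesh import CellType, Mesh

__all__ = ["EndoBoundary", "register_endo_boundary", "enforce_corridors"]


@dataclass
class EndoBoundary:
    """A vessel corridor: two rays ``anchor ± half_width * n̂`` extending
    along ``direction`` (outward unit vector), with n̂ ⟂ direction."""

    anchor: np.ndarray
    direction: np.ndarray
    half_width: float
    active: bool = True

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, float)
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("corridor direction must be nonzero")
        self.direction = d / n

    @property
    def normal(self) -> np.ndarray:
        d = self.direction
        return np.array([-d[1], d[0]])

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor.tolist(),
            "direction": self.direction.tolist(),
            "half_width": self.half_width,
            "active": self.active,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EndoBoundary":
        return cls(
            anchor=d["anchor"],
            direction=d["direction"],
            half_width=d["half_width"],
            active=d.get("active", True),
        )


def epithelial_only_vertices(mesh: Mesh) -> np.ndarray:
    """Vertex ids used by epithelial cells and by no other cell type."""
    epi: set[int] = set()
    for cell in mesh.cells.values():
        if cell.type.is_epithelial:
            epi.update(cell.ring)
    for cell in mesh.cells.values():
        if not cell.type.is_epithelial:
            epi.difference_update(cell.ring)
    return np.array(sorted(epi), dtype=int)


def register_endo_boundary(
    mesh: Mesh, stalk_cell_id: int, fix_vertices: bool = True
) -> EndoBoundary:
    """Create the corridor for a peripheral stalk cell and fix its
    boundary vertices.

    The corridor is anchored at the stalk centroid and directed along
    the outward normal of the stalk's free boundary; its half-width is
    half the stalk's boundary-edge span.
    """
    cell = mesh.cells[stalk_cell_id]
    if cell.type is not CellType.ENDO_STALK:
        raise ValueError(f"cell {stalk_cell_id} is not a stalk cell")
    bedges = mesh.cell_boundary_edges(stalk_cell_id)
    if not bedges:
        raise ValueError(f"stalk cell {stalk_cell_id} does not touch the boundary")

    # anchor on the stalk's free surface (mean of its boundary vertices)
    # so the corridor opens outward of the tissue, not through the
    # flanking epithelium; outward normal from the boundary edges (cell
    # is CCW, so the interior lies left of each directed boundary edge)
    normal = np.zeros(2)
    bverts = set()
    for a, b in bedges:
        d = mesh.positions[b] - mesh.positions[a]
        normal += np.array([d[1], -d[0]])
        bverts.update((a, b))
    anchor = mesh.positions[sorted(bverts)].mean(axis=0)
    n = np.linalg.norm(normal)
    if n < 1e-12:
        centroid_all = mesh.positions[mesh.alive_mask].mean(axis=0)
        normal = anchor - centroid_all
        n = np.linalg.norm(normal)
    direction = normal / n

    pts = mesh.positions[sorted(bverts)]
    lateral = pts @ np.array([-direction[1], direction[0]])
    half_width = 0.5 * float(lateral.max() - lateral.min())

    if fix_vertices:
        for v in bverts:
            mesh.fix_vertex(v)
    return EndoBoundary(anchor=anchor, direction=direction, half_width=half_width)


def enforce_corridors(
    mesh: Mesh,
    boundaries: Sequence[EndoBoundary],
    vertex_ids=None,
) -> int:
    """Project epithelial vertices out of every active corridor.

    A vertex strictly between the two rays, outward of the anchor, is
    moved to the nearest point of the nearer ray (ties resolved toward
    the vertex's own side). Endothelial and lumen vertices are
    untouched. Returns the number of vertices relocated. Idempotent.
    """
    active = [b for b in boundaries if b.active]
    if not active:
        return 0
    if vertex_ids is None:
        vertex_ids = epithelial_only_vertices(mesh)
    vids = np.asarray(vertex_ids, dtype=int)
    if vids.size == 0:
        return 0
    vids = vids[~mesh.fixed_mask[vids]]
    pos = mesh.positions
    moved = np.zeros(len(vids), bool)
    for b in active:
        rel = pos[vids] - b.anchor
        t = rel @ b.direction
        u = rel @ b.normal
        inside = (t > 0) & (np.abs(u) < b.half_width)
        if not inside.any():
            continue
        u_new = np.where(u[inside] >= 0, b.half_width, -b.half_width)
        pos[vids[inside]] = (
            b.anchor
            + t[inside, None] * b.direction
            + u_new[:, None] * b.normal
        )
        moved |= inside
    return int(moved.sum())
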