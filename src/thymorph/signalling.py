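"""VEGF morphogen field and endothelial chemotaxis.

Every epithelial cell is a VEGF source; the morphogen diffuses across
the tissue and degrades, with the concentration pinned to zero at the
tissue boundary. The steady state of

    dc/dt = D lap(c) + s * 1{epithelial} - k_deg * c

is solved quasi-statically on the dual graph of cell adjacency by a
finite-volume scheme: the flux between adjacent cells is weighted by
shared-edge length over centre distance, and each balance is scaled by
the cell's area. The resulting centro-peripheral gradient drives
endothelial tip cells inward via a motile force on their vertices.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import CellType, Mesh

__all__ = [
    "MorphogenParams",
    "ChemotaxisParams",
    "MorphogenField",
    "solve_vegf_field",
    "vegf_gradient",
    "tip_motile_forces",
]


@dataclass
class MorphogenParams:
    """Reaction-diffusion coefficients (nondimensional defaults).

    ``source_rate`` = 0 is the in-silico VEGFA-knockout mode.
    """

    diffusivity: float = 1.0  # D, length^2 / h
    source_rate: float = 1.0  # s, conc / h, per epithelial cell
    degradation: float = 1.0  # k_deg, 1 / h

    def __post_init__(self):
        if self.diffusivity <= 0 or self.degradation <= 0:
            raise ValueError("diffusivity and degradation must be positive")
        if self.source_rate < 0:
            raise ValueError("source_rate must be >= 0")


@dataclass
class ChemotaxisParams:
    """Tip-cell motile response to the VEGF gradient."""

    motile_force: float = 2.5  # mu, force units
    gradient_floor: float = 1e-6  # |grad c| below which tips idle


@dataclass
class MorphogenField:
    """Per-cell concentration and least-squares gradient."""

    concentration: Dict[int, float] = field(default_factory=dict)
    gradient: Dict[int, np.ndarray] = field(default_factory=dict)


def _boundary_cells(mesh: Mesh) -> set:
    out = set()
    for e, cids in mesh.edge_map.items():
        if len(cids) == 1:
            out.add(cids[0])
    return out


def solve_vegf_field(
    mesh: Mesh,
    params: MorphogenParams,
    dirichlet_cells: Optional[Sequence[int]] = None,
) -> MorphogenField:
    """Steady-state VEGF field on the cell-adjacency dual graph.

    Dirichlet c = 0 is imposed on ``dirichlet_cells`` (default: every
    cell with a free boundary edge). The positive degradation rate
    keeps the system non-singular even on components with no boundary
    cell. Returns concentrations plus per-cell gradients.
    """
    if not mesh.cells:
        return MorphogenField()
    cids, areas_raw, centroids = mesh.geometry_table()
    index = {cid: i for i, cid in enumerate(cids)}
    n = len(cids)
    if dirichlet_cells is None:
        dirichlet = _boundary_cells(mesh)
    else:
        dirichlet = set(dirichlet_cells)
    areas = np.maximum(areas_raw, 1e-9)

    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    diag = params.degradation * np.ones(n)
    rhs = np.array(
        [
            params.source_rate if mesh.cells[c].type.is_epithelial else 0.0
            for c in cids
        ]
    )
    pos = mesh.positions
    for (a, b), adj in mesh.edge_map.items():
        if len(adj) != 2:
            continue
        i, j = index[adj[0]], index[adj[1]]
        face = float(np.linalg.norm(pos[a] - pos[b]))
        dist = float(np.linalg.norm(centroids[i] - centroids[j]))
        if dist < 1e-9:
            continue
        w = params.diffusivity * face / dist
        for (r, c) in ((i, j), (j, i)):
            rows.append(r)
            cols.append(c)
            vals.append(-w / areas[r])
            diag[r] += w / areas[r]

    A = (
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n)) + sp.diags(diag)
    ).tocsr()
    # Dirichlet rows: c_i = 0
    d_idx = np.array([index[c] for c in dirichlet if c in index], dtype=int)
    if len(d_idx):
        A = A.tolil()
        for i in d_idx:
            A.rows[i] = [i]
            A.data[i] = [1.0]
        A = A.tocsr()
        rhs[d_idx] = 0.0
    conc = spla.spsolve(A, rhs)
    conc = np.maximum(conc, 0.0)

    fieldv = MorphogenField()
    for cid, c in zip(cids, conc):
        fieldv.concentration[cid] = float(c)
    nbr_map = mesh.neighbor_map
    for cid in cids:
        fieldv.gradient[cid] = _lsq_gradient(
            fieldv.concentration, cid, nbr_map[cid], centroids, index
        )
    return fieldv


def _lsq_gradient(conc, cid, nbrs, centroids, index) -> np.ndarray:
    """Plane-fit gradient via 2x2 normal equations; zero when fewer than
    two non-collinear neighbour displacements exist."""
    if len(nbrs) < 2:
        return np.zeros(2)
    ci = centroids[index[cid]]
    dx = centroids[[index[j] for j in nbrs]] - ci
    dc = np.array([conc[j] - conc[cid] for j in nbrs])
    g11 = dx[:, 0] @ dx[:, 0]
    g12 = dx[:, 0] @ dx[:, 1]
    g22 = dx[:, 1] @ dx[:, 1]
    det = g11 * g22 - g12 * g12
    if det < 1e-12 * max(g11 + g22, 1e-30) ** 2:
        return np.zeros(2)
    b1 = dx[:, 0] @ dc
    b2 = dx[:, 1] @ dc
    return np.array([(g22 * b1 - g12 * b2) / det, (g11 * b2 - g12 * b1) / det])


def vegf_gradient(field: MorphogenField, mesh: Mesh, cell_id: int) -> np.ndarray:
    """Least-squares gradient of the solved field at a cell."""
    if cell_id in field.gradient:
        return field.gradient[cell_id]
    cids, _, centroids = mesh.geometry_table()
    index = {c: i for i, c in enumerate(cids)}
    return _lsq_gradient(
        field.concentration, cell_id, mesh.neighbor_map[cell_id], centroids, index
    )


def tip_motile_forces(
    mesh: Mesh,
    field: MorphogenField,
    params: ChemotaxisParams,
) -> np.ndarray:
    """Additive chemotactic force, one row per vertex.

    Every vertex of every tip cell receives mu * grad(c)/|grad(c)|
    evaluated at that cell; zero where the gradient is below the floor.
    """
    forces = np.zeros_like(mesh.positions)
    if params.motile_force == 0:
        return forces
    for cell in mesh.cells_of_type(CellType.ENDO_TIP):
        g = field.gradient.get(cell.id)
        if g is None:
            continue
        mag = np.linalg.norm(g)
        if mag < params.gradient_floor:
            continue
        f = params.motile_force * g / mag
        for vid in cell.ring:
            forces[vid] += f
    return forces
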