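"""Tissue energy, vertex forces and forward-Euler time stepping.

The tissue energy is the standard vertex-model functional

    E = sum_cells K/2 (A - A0)^2 + sum_edges Lambda_j L_j
        + sum_cells Gamma/2 P^2

with area elasticity K, per-cell target area A0, line tension Lambda
resolved per unordered pair of adjacent cell types (differential
adhesion; the free tissue boundary counts as the pseudo-type
``"boundary"``), and perimeter contractility Gamma. Vertices move with
unit mobility down the energy gradient, F_k = -grad_k E, integrated by
forward Euler.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .mesh import BOUNDARY, Cell, CellType, Mesh

__all__ = [
    "EnergyParameters",
    "ForceEvaluator",
    "total_energy",
    "vertex_forces",
    "euler_step",
    "SimulationInstabilityError",
    "MissingTensionError",
]


class SimulationInstabilityError(RuntimeError):
    """Raised when forces or positions become non-finite."""


class MissingTensionError(KeyError):
    """A cell-type pair sharing an edge has no line-tension entry."""


def _pair_key(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EnergyParameters:
    """Mechanical parameters of the tissue energy.

    ``K``/``Gamma``/``A0_init`` are keyed by cell type; ``Lambda`` by
    the unordered pair of the two cell types adjacent to an edge (or a
    type and ``"boundary"`` for free edges). A0 itself is per-cell
    state; ``A0_init`` only seeds newly created cells.
    """

    K: Dict[CellType, float] = field(default_factory=dict)
    Gamma: Dict[CellType, float] = field(default_factory=dict)
    A0_init: Dict[CellType, float] = field(default_factory=dict)
    Lambda: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def line_tension(self, type_a: str, type_b: str) -> float:
        key = _pair_key(type_a, type_b)
        try:
            return self.Lambda[key]
        except KeyError as exc:
            raise MissingTensionError(
                f"no line tension for edge type pair {key}"
            ) from exc

    def set_lambda(self, type_a, type_b, value: float) -> None:
        a = type_a.value if isinstance(type_a, CellType) else str(type_a)
        b = type_b.value if isinstance(type_b, CellType) else str(type_b)
        self.Lambda[_pair_key(a, b)] = value

    @classmethod
    def default(cls) -> "EnergyParameters":
        """Calibrated default parameterisation (nondimensional units:
        lengths in cell diameters, epithelial A0 = 1).

        Epithelial-epithelial tension is set high enough (cohesion low
        enough) that endothelial tip cells can intercalate; endothelial
        cells adhere strongly to each other (low tension) so stalk
        chains stay coherent behind a migrating tip.
        """
        p = cls(
            K={
                CellType.EPI_CENTRAL: 1.0,
                CellType.EPI_PERIPHERAL: 1.0,
                CellType.ENDO_TIP: 20.0,
                CellType.ENDO_STALK: 20.0,
                CellType.LUMEN: 2.0,
            },
            Gamma={
                CellType.EPI_CENTRAL: 0.04,
                CellType.EPI_PERIPHERAL: 0.04,
                CellType.ENDO_TIP: 0.04,
                CellType.ENDO_STALK: 0.04,
                CellType.LUMEN: 0.02,
            },
            A0_init={
                CellType.EPI_CENTRAL: 1.0,
                CellType.EPI_PERIPHERAL: 1.0,
                CellType.ENDO_TIP: 0.22,
                CellType.ENDO_STALK: 0.22,
                CellType.LUMEN: 0.1,
            },
        )
        ec, ep = CellType.EPI_CENTRAL.value, CellType.EPI_PERIPHERAL.value
        tip, stk = CellType.ENDO_TIP.value, CellType.ENDO_STALK.value
        lum = CellType.LUMEN.value
        epi = [ec, ep]
        endo = [tip, stk]
        # epithelial-epithelial: weak cohesion (higher tension) so the
        # sheet can be peeled apart by invading endothelium
        for a in epi:
            for b in epi:
                p.set_lambda(a, b, 0.12)
        # endothelial-endothelial: strong mutual adhesion
        for a in endo:
            for b in endo:
                p.set_lambda(a, b, 0.02)
        # heterotypic epithelial-endothelial: intermediate
        for a in epi:
            for b in endo:
                p.set_lambda(a, b, 0.06)
        # lumen faces epithelium with low tension (apical surface)
        for a in epi:
            p.set_lambda(lum, a, 0.05)
        p.set_lambda(lum, lum, 0.05)
        for b in endo:
            p.set_lambda(lum, b, 0.10)
        # free boundary tensions
        for a in epi:
            p.set_lambda(a, BOUNDARY, 0.15)
        for b in endo:
            p.set_lambda(b, BOUNDARY, 0.10)
        p.set_lambda(lum, BOUNDARY, 0.15)
        return p


def cohesive_energy_parameters() -> EnergyParameters:
    """High epithelial cohesion variant (epithelial adhesiveness turned
    down): every interface involving an epithelial cell carries a high
    tension, and heterotypic epithelium-endothelium contact becomes
    prohibitively costly. In this regime endothelial tip cells fail to
    invade the epithelial mass; the default parameterisation (reduced
    epithelial cohesion) is what permits invasion and tissue fission.
    """
    p = EnergyParameters.default()
    epi = [CellType.EPI_CENTRAL.value, CellType.EPI_PERIPHERAL.value]
    endo = [CellType.ENDO_TIP.value, CellType.ENDO_STALK.value]
    for a in epi:
        for b in epi:
            p.set_lambda(a, b, 1.5)
        for b in endo:
            p.set_lambda(a, b, 4.0)
    return p


class ForceEvaluator:
    """Vectorised energy/force evaluation with a cached flattened topology.

    ``refresh()`` rebuilds the flat ring and edge arrays after any
    topological change; ``sync_states()`` re-reads per-cell target
    areas (which drift every step as cells grow). The hot path
    (``forces()``) is pure numpy.
    """

    def __init__(self, mesh: Mesh, params: EnergyParameters):
        self.mesh = mesh
        self.params = params
        self._version = -1
        self.refresh()

    # -- cache construction -------------------------------------------
    def refresh(self) -> None:
        mesh, params = self.mesh, self.params
        self.cell_ids = sorted(mesh.cells)
        cindex = {cid: i for i, cid in enumerate(self.cell_ids)}
        ring_v, ring_prev, ring_next, ring_cell = [], [], [], []
        for cid in self.cell_ids:
            ring = mesh.cells[cid].ring
            n = len(ring)
            for i in range(n):
                ring_v.append(ring[i])
                ring_prev.append(ring[i - 1])
                ring_next.append(ring[(i + 1) % n])
                ring_cell.append(cindex[cid])
        self.ring_v = np.asarray(ring_v, dtype=np.int64)
        self.ring_prev = np.asarray(ring_prev, dtype=np.int64)
        self.ring_next = np.asarray(ring_next, dtype=np.int64)
        self.ring_cell = np.asarray(ring_cell, dtype=np.int64)

        self.cell_K = np.array(
            [params.K[mesh.cells[cid].type] for cid in self.cell_ids]
        )
        self.cell_Gamma = np.array(
            [params.Gamma[mesh.cells[cid].type] for cid in self.cell_ids]
        )

        em = mesh.edge_map
        ea, eb, lam = [], [], []
        for (a, b), cids in sorted(em.items()):
            types = [mesh.cells[c].type.value for c in cids]
            if len(types) == 1:
                types.append(BOUNDARY)
            ea.append(a)
            eb.append(b)
            lam.append(params.line_tension(types[0], types[1]))
        self.edge_a = np.asarray(ea, dtype=np.int64)
        self.edge_b = np.asarray(eb, dtype=np.int64)
        self.edge_lambda = np.asarray(lam)
        self.sync_states()
        self._version = mesh.topology_version

    def sync_states(self) -> None:
        self.cell_A0 = np.array(
            [self.mesh.cells[cid].state.target_area for cid in self.cell_ids]
        )

    def ensure_fresh(self) -> None:
        if self._version != self.mesh.topology_version:
            self.refresh()

    # -- evaluation ----------------------------------------------------
    def _areas_perimeters(self, pos: np.ndarray):
        rv = pos[self.ring_v]
        rn = pos[self.ring_next]
        cross = rv[:, 0] * rn[:, 1] - rn[:, 0] * rv[:, 1]
        ncells = len(self.cell_ids)
        areas = 0.5 * np.bincount(self.ring_cell, weights=cross, minlength=ncells)
        seg = np.linalg.norm(rn - rv, axis=1)
        perims = np.bincount(self.ring_cell, weights=seg, minlength=ncells)
        return areas, perims

    def energy(self) -> float:
        self.ensure_fresh()
        pos = self.mesh.positions
        areas, perims = self._areas_perimeters(pos)
        e_area = 0.5 * np.sum(self.cell_K * (areas - self.cell_A0) ** 2)
        e_perim = 0.5 * np.sum(self.cell_Gamma * perims**2)
        lengths = np.linalg.norm(pos[self.edge_a] - pos[self.edge_b], axis=1)
        e_edge = np.sum(self.edge_lambda * lengths)
        return float(e_area + e_edge + e_perim)

    def forces(self) -> np.ndarray:
        self.ensure_fresh()
        pos = self.mesh.positions
        nv = pos.shape[0]
        areas, perims = self._areas_perimeters(pos)

        rv = pos[self.ring_v]
        rp = pos[self.ring_prev]
        rn = pos[self.ring_next]

        # grad of cell area wrt ring vertex: 0.5 * (d_y, -d_x), d = next - prev
        d = rn - rp
        grad_a = 0.5 * np.column_stack([d[:, 1], -d[:, 0]])

        # grad of cell perimeter wrt ring vertex
        e1 = rv - rp
        e2 = rv - rn
        l1 = np.linalg.norm(e1, axis=1)
        l2 = np.linalg.norm(e2, axis=1)
        np.maximum(l1, 1e-30, out=l1)
        np.maximum(l2, 1e-30, out=l2)
        grad_p = e1 / l1[:, None] + e2 / l2[:, None]

        coef_a = (self.cell_K * (areas - self.cell_A0))[self.ring_cell]
        coef_p = (self.cell_Gamma * perims)[self.ring_cell]
        contrib = -coef_a[:, None] * grad_a - coef_p[:, None] * grad_p

        fx = np.bincount(self.ring_v, weights=contrib[:, 0], minlength=nv)
        fy = np.bincount(self.ring_v, weights=contrib[:, 1], minlength=nv)

        # line tension: -Lambda * dL/dr
        dvec = pos[self.edge_a] - pos[self.edge_b]
        ln = np.linalg.norm(dvec, axis=1)
        np.maximum(ln, 1e-30, out=ln)
        t = self.edge_lambda[:, None] * dvec / ln[:, None]
        fx += np.bincount(self.edge_a, weights=-t[:, 0], minlength=nv)
        fy += np.bincount(self.edge_a, weights=-t[:, 1], minlength=nv)
        fx += np.bincount(self.edge_b, weights=t[:, 0], minlength=nv)
        fy += np.bincount(self.edge_b, weights=t[:, 1], minlength=nv)
        return np.column_stack([fx, fy])

    def cell_areas(self) -> np.ndarray:
        self.ensure_fresh()
        areas, _ = self._areas_perimeters(self.mesh.positions)
        return areas


# ----------------------------------------------------------------------
# functional wrappers (convenient for tests and small meshes)
# ----------------------------------------------------------------------
def total_energy(mesh: Mesh, params: EnergyParameters) -> float:
    return ForceEvaluator(mesh, params).energy()


def vertex_forces(mesh: Mesh, params: EnergyParameters) -> np.ndarray:
    """Force per vertex row-indexed like ``mesh.positions``. Forces on
    fixed vertices are computed here and masked in :func:`euler_step`."""
    return ForceEvaluator(mesh, params).forces()


def euler_step(mesh: Mesh, forces: np.ndarray, dt: float) -> None:
    """Advance vertex positions by ``forces * dt`` (unit mobility).

    Fixed vertices do not move. The simulation clock advances by dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(forces[mesh.alive_mask])):
        raise SimulationInstabilityError(
            f"non-finite force at t={mesh.time:.4f} h"
        )
    mobile = mesh.alive_mask & ~mesh.fixed_mask
    mesh.positions[mobile] += forces[mobile] * dt
    mesh.time += dt
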