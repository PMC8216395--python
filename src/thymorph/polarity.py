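"""Apico-basal polarity dynamics and follicular lumen formation.

Every epithelial cell carries a polarity vector p whose direction
points basal-to-apical and whose magnitude is the cell's polarisation
degree. Cues accumulate each step:

* an endothelial neighbour or a stretch of free tissue boundary pushes
  p away from itself at rate rho (the apical pole turns away from the
  basal contact);
* a developed lumen or a strongly polarised neighbour attracts p (the
  same rule with negative rate), so apical poles converge on a shared
  lumen;
* neighbouring epithelial cells adjust the magnitude by -/+ eps*cos(theta),
  theta being the angle between p and the centre-to-centre direction.

A cell polarised beyond ``p_star`` and older than ``age_min`` divides
perpendicular to p; the distal daughter (along +p) becomes a lumen
cell — a non-proliferating cell type standing in for the fluid-filled
cavity, which a vertex model cannot represent as a hole. Lumen target
area then grows at a pace set by the polarity of the surrounding
epithelium.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .mesh import CellState, CellType, Mesh
from .rearrange import DivisionError, divide_cell

__all__ = [
    "PolarityParams",
    "LumenParams",
    "update_polarity",
    "check_polarised_division",
    "create_lumen",
    "grow_lumina",
]


@dataclass
class PolarityParams:
    """Rates and thresholds of the polarity model (per hour).

    The boundary cue is weaker than the endothelial one (the free
    periphery polarises epithelium less than vessel contact does);
    ``attract_developed`` flips the sign convention of the epithelial
    magnitude term.
    """

    rho_endothelial: float = 0.009
    rho_periphery: float = 0.0045
    rho_lumen: float = 0.015  # magnitude of the (negative-rate) lumen cue
    epsilon: float = 0.008
    p_star: float = 0.6
    p_max: float = 1.0
    age_min: float = 2.0
    developed_lumen_area: float = 0.2  # lumen counts as developed above this
    # area (2x the default initial lumen area)
    attract_developed: bool = True

    def strong(self, p: np.ndarray) -> bool:
        return float(np.linalg.norm(p)) > self.p_star


@dataclass
class LumenParams:
    """Lumen creation and growth."""

    initial_area: float = 0.1
    growth_coefficient: float = 0.03  # area per unit neighbour polarity per h


def _adjacency(mesh: Mesh):
    """Per-cell neighbour lists and boundary-edge midpoints (cached
    topology, fresh positions)."""
    nbrs = mesh.neighbor_map
    pos = mesh.positions
    bmids: Dict[int, List[np.ndarray]] = {}
    for cid, edges in mesh.cell_boundary_edge_map.items():
        bmids[cid] = [0.5 * (pos[a] + pos[b]) for a, b in edges]
    return nbrs, bmids


def update_polarity(mesh: Mesh, params: PolarityParams, dt: float) -> None:
    """Advance every epithelial polarity vector by one increment.

    All cues are evaluated on the state at the start of the call
    (synchronous update); |p| is clamped to ``p_max``. Endothelial and
    lumen cells always carry zero polarity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nbrs = mesh.neighbor_map
    bedges = mesh.cell_boundary_edge_map
    cids_list, areas, cent = mesh.geometry_table()
    gidx = {cid: i for i, cid in enumerate(cids_list)}
    pos = mesh.positions
    cells = mesh.cells

    epi = [cid for cid in cids_list if cells[cid].type.is_epithelial]
    if not epi:
        for cid in cids_list:
            cells[cid].state.polarity[:] = 0.0
        return
    eidx = {cid: i for i, cid in enumerate(epi)}
    P = np.array([cells[cid].state.polarity for cid in epi], dtype=float)
    strong = np.linalg.norm(P, axis=1) > params.p_star

    # pair lists (cell index, cue point); batched below
    endo_i, endo_pt = [], []  # endothelial-neighbour cues, rate rho_endothelial
    bnd_i, bnd_pt = [], []  # boundary-midpoint cues, rate rho_periphery
    att_i, att_pt = [], []  # lumen / strongly-polarised cues, rate -rho_lumen
    eps_i, eps_pt = [], []  # epithelial magnitude-modulation pairs
    for i, cid in enumerate(epi):
        for nid in nbrs[cid]:
            ntype = cells[nid].type
            if ntype.is_endothelial:
                endo_i.append(i)
                endo_pt.append(cent[gidx[nid]])
            elif ntype is CellType.LUMEN:
                if areas[gidx[nid]] > params.developed_lumen_area:
                    att_i.append(i)
                    att_pt.append(cent[gidx[nid]])
            elif strong[eidx[nid]]:
                att_i.append(i)
                att_pt.append(cent[gidx[nid]])
                eps_i.append(i)
                eps_pt.append(cent[gidx[nid]])
        for a, b in bedges.get(cid, ()):
            bnd_i.append(i)
            bnd_pt.append(0.5 * (pos[a] + pos[b]))

    epi_cent = cent[[gidx[c] for c in epi]]
    dP = np.zeros_like(P)

    def accumulate(idx_list, pt_list, rate):
        if not idx_list:
            return
        ii = np.asarray(idx_list)
        d = epi_cent[ii] - np.asarray(pt_list)
        dist = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        contrib = rate * d / dist[:, None] * dt
        np.add.at(dP, ii, contrib)

    # (i)+(ii): endothelial neighbours and free-boundary midpoints push
    # p away from themselves; (iii) developed lumina and strongly
    # polarised neighbours attract (negative rate)
    accumulate(endo_i, endo_pt, params.rho_endothelial)
    accumulate(bnd_i, bnd_pt, params.rho_periphery)
    accumulate(att_i, att_pt, -params.rho_lumen)
    P_new = P + dP

    # epithelial magnitude modulation -/+ eps*cos(theta), theta between
    # p and the direction to the neighbour (snapshot state)
    if eps_i:
        ii = np.asarray(eps_i)
        toward = np.asarray(eps_pt) - epi_cent[ii]
        toward /= np.maximum(
            np.linalg.norm(toward, axis=1), 1e-12
        )[:, None]
        mags = np.maximum(np.linalg.norm(P_new[ii], axis=1), 1e-12)
        cos_t = np.clip(
            np.einsum("ij,ij->i", P_new[ii] / mags[:, None], toward), -1, 1
        )
        sign = -1.0 if params.attract_developed else 1.0
        dmag = np.zeros(len(epi))
        np.add.at(dmag, ii, sign * params.epsilon * cos_t * dt)
        mag_all = np.linalg.norm(P_new, axis=1)
        nz = mag_all > 1e-12
        scale = np.ones(len(epi))
        scale[nz] = np.maximum(mag_all[nz] + dmag[nz], 0.0) / mag_all[nz]
        P_new *= scale[:, None]

    mag_all = np.linalg.norm(P_new, axis=1)
    over = mag_all > params.p_max
    P_new[over] *= (params.p_max / mag_all[over])[:, None]

    for i, cid in enumerate(epi):
        cells[cid].state.polarity = P_new[i]
    for cid in cids_list:
        if not cells[cid].type.is_epithelial:
            cells[cid].state.polarity[:] = 0.0


def check_polarised_division(
    mesh: Mesh, params: PolarityParams
) -> List[int]:
    """Epithelial cells eligible to create a lumen: |p| > p_star, age >
    age_min, and not already touching a lumen cell (those contribute to
    the existing lumen instead)."""
    nbrs = mesh.neighbor_map
    out: List[int] = []
    for cid in sorted(mesh.cells):
        cell = mesh.cells[cid]
        if not cell.type.is_epithelial:
            continue
        if np.linalg.norm(cell.state.polarity) <= params.p_star:
            continue
        if cell.state.age <= params.age_min:
            continue
        if any(
            mesh.cells[n].type is CellType.LUMEN for n in nbrs[cid]
        ):
            continue
        out.append(cid)
    return out


def create_lumen(
    mesh: Mesh,
    cell_id: int,
    params: LumenParams,
) -> Optional[int]:
    """Divide an eligible cell perpendicular to its polarity vector;
    the distal daughter becomes the lumen cell.

    Returns the lumen cell id, or None when the division is
    geometrically impossible this step (the cell is skipped).
    """
    cell = mesh.cells[cell_id]
    p = cell.state.polarity
    mag = np.linalg.norm(p)
    if mag < 1e-12:
        return None
    axis = np.array([-p[1], p[0]]) / mag  # division line perpendicular to p
    mother_state = cell.state.copy()
    try:
        d1, d2 = divide_cell(mesh, cell_id, axis=axis)
    except DivisionError:
        return None
    s1 = float((mesh.cell_centroid(mesh.cells[d1]) @ p))
    s2 = float((mesh.cell_centroid(mesh.cells[d2]) @ p))
    distal, proximal = (d1, d2) if s1 >= s2 else (d2, d1)

    lum = mesh.cells[distal]
    lum.type = CellType.LUMEN
    lum.state = CellState(
        age=0.0,
        generation=mother_state.generation,
        cycle_duration=np.inf,
        target_area=params.initial_area,
        polarity=np.zeros(2),
    )
    prox = mesh.cells[proximal]
    prox.state = mother_state  # the proximal daughter replaces the mother
    mesh.bump()
    return distal


def grow_lumina(mesh: Mesh, params: LumenParams, dt: float) -> None:
    """Increase each lumen's target area in proportion to the summed
    polarity magnitude of its adjacent epithelial cells. Target areas
    never decrease."""
    nbrs = mesh.neighbor_map
    for cid in sorted(mesh.cells):
        cell = mesh.cells[cid]
        if cell.type is not CellType.LUMEN:
            continue
        drive = sum(
            float(np.linalg.norm(mesh.cells[n].state.polarity))
            for n in nbrs[cid]
            if mesh.cells[n].type.is_epithelial
        )
        if drive > 0:
            cell.state.target_area += params.growth_coefficient * drive * dt
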