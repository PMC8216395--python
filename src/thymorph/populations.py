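"""Cell populations: peripheral/central classification, phase-dependent
epithelial cell cycles, elongation-triggered stalk division and
periodic addition of new endothelial branches.

Epithelial cells carry a timed cycle whose duration depends on where
they sit: peripheral cells (touching the free tissue boundary, or by
extension an endothelial cell) cycle in 11 h 20 min, central cells in
31 h 52 min — values derived from EdU labelling of the embryonic mouse
thyroid. Each generation multiplies the duration by a generation
factor g >= 1, reproducing the exponential slow-down of proliferation
over developmental time. Endothelial tip cells are terminally
differentiated and never divide; stalk cells divide on shape, when
their elongation factor crosses a threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import elongation_factor as _elong
from .mesh import Cell, CellState, CellType, Mesh
from .rearrange import DivisionError, divide_cell

__all__ = [
    "ProliferationParams",
    "EndothelialParams",
    "classify_peripherality",
    "cycle_duration_at_birth",
    "advance_cycles_and_divide",
    "elongation_factor",
    "stalk_divide_if_elongated",
    "add_endothelial_branch",
    "proliferating_fraction",
    "grow_target_areas",
]

#: 11 h 20 min and 31 h 52 min, in hours
T_PERIPHERAL = 11.0 + 20.0 / 60.0
T_CENTRAL = 31.0 + 52.0 / 60.0


@dataclass
class ProliferationParams:
    """Epithelial cell-cycle parameters.

    ``generation_factor`` g multiplies the cycle duration at every
    generation so lineages slow down; the default is calibrated so the
    in-silico proliferating fraction decays from ~45% toward ~10% over
    four simulated days. ``cycle_jitter`` is the s.d. of a lognormal
    multiplier applied at birth to desynchronise division waves.
    ``edu_window`` is the S-phase-proxy window used for reporting the
    proliferating fraction (cells within 0.5 h of dividing).
    """

    T_peripheral: float = T_PERIPHERAL
    T_central: float = T_CENTRAL
    generation_factor: float = 1.45
    cycle_jitter: float = 0.1
    edu_window: float = 0.5

    def __post_init__(self):
        if self.generation_factor < 1:
            raise ValueError("generation_factor must be >= 1")


@dataclass
class EndothelialParams:
    """Stalk division and branch-addition parameters.

    New tip+stalk branches appear on the periphery at
    ``branch_addition_rate`` per hour during the first
    ``branch_addition_cutoff`` hours, mirroring the window in which
    new peripheral endothelium can be recruited stably.
    """

    elongation_threshold: float = 3.4
    branch_addition_rate: float = 0.05
    branch_addition_cutoff: float = 24.0
    branch_cell_area: float = 0.22  # target area handed to new endothelial cells
    branch_extrusion_depth: float = 0.45  # quad depth, in cell diameters
    stalk_regrowth_time: float = 16.0  # hours for a stalk daughter to regrow A0
    min_division_area: float = 0.16  # a stalk must have regrown this far to divide

    def __post_init__(self):
        if self.elongation_threshold <= 1:
            raise ValueError("elongation_threshold must exceed 1")


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------
def classify_peripherality(
    mesh: Mesh, endothelial_contact_counts: bool = True
) -> Dict[int, CellType]:
    """Relabel every epithelial cell as peripheral or central.

    Peripheral: at least one edge not shared with another cell (free
    boundary), or — by the extended definition, reflecting that the
    periphery is wherever epithelium touches ECM or vessels — at least
    one edge shared with an endothelial cell. All other epithelial
    cells are central. Endothelial and lumen cells are untouched.
    """
    labels: Dict[int, CellType] = {}
    bedge_map = mesh.cell_boundary_edge_map
    nbr_map = mesh.neighbor_map
    for cid in sorted(mesh.cells):
        cell = mesh.cells[cid]
        if not cell.type.is_epithelial:
            continue
        peripheral = bool(bedge_map.get(cid))
        if not peripheral and endothelial_contact_counts:
            peripheral = any(
                mesh.cells[n].type.is_endothelial for n in nbr_map.get(cid, ())
            )
        new_type = CellType.EPI_PERIPHERAL if peripheral else CellType.EPI_CENTRAL
        if new_type is not cell.type:
            cell.type = new_type
            mesh.bump()
        labels[cid] = new_type
    return labels


# ----------------------------------------------------------------------
# cell cycles
# ----------------------------------------------------------------------
def cycle_duration_at_birth(
    ctype: CellType,
    generation: int,
    params: ProliferationParams,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """T_type * g^generation, optionally lognormal-jittered."""
    if not ctype.is_epithelial:
        raise ValueError(f"cycle duration undefined for {ctype}")
    base = (
        params.T_peripheral
        if ctype is CellType.EPI_PERIPHERAL
        else params.T_central
    )
    dur = base * params.generation_factor**generation
    if rng is not None and params.cycle_jitter > 0:
        s = params.cycle_jitter
        dur *= float(rng.lognormal(-0.5 * s * s, s))
    return dur


def advance_cycles_and_divide(
    mesh: Mesh,
    params: ProliferationParams,
    dt: float,
    rng: Optional[np.random.Generator] = None,
    skip: Optional[set] = None,
) -> List[dict]:
    """Advance all cell ages by ``dt`` and divide epithelial cells whose
    age reached their cycle duration.

    Daughters start at age 0, generation +1, a freshly sampled
    duration, and half the mother's target area (regrowing linearly
    over their cycle). Tip cells never divide; stalk division is
    shape-triggered elsewhere; lumen cells never proliferate. Cells in
    ``skip`` (e.g. ones that just underwent a polarity-triggered
    division) are exempt this call.
    """
    skip = skip or set()
    events: List[dict] = []
    for cid in sorted(mesh.cells):
        cell = mesh.cells.get(cid)
        if cell is None:
            continue
        cell.state.age += dt
    for cid in sorted(mesh.cells):
        cell = mesh.cells.get(cid)
        if cell is None or cid in skip:
            continue
        if not cell.type.is_epithelial:
            continue
        st = cell.state
        if st.age < st.cycle_duration:
            continue
        try:
            d1, d2 = divide_cell(mesh, cid)
        except DivisionError:
            st.age = st.cycle_duration - 0.5  # retry shortly with new geometry
            continue
        gen = st.generation + 1
        for did in (d1, d2):
            ds = mesh.cells[did].state
            ds.age = 0.0
            ds.generation = gen
            ds.target_area = 0.5 * st.target_area
            ds.cycle_duration = cycle_duration_at_birth(
                mesh.cells[did].type, gen, params, rng
            )
            ds.polarity = st.polarity.copy()
        events.append(
            {
                "time": mesh.time,
                "cell": cid,
                "event": "epithelial_division",
                "daughters": (d1, d2),
                "generation": gen,
            }
        )
    return events


def grow_target_areas(
    mesh: Mesh,
    final_area: Dict[CellType, float],
    dt: float,
    prolif: ProliferationParams,
    endo: EndothelialParams,
) -> None:
    """Linear target-area growth: epithelial cells from A0/2 at birth to
    the type's full A0 over one cycle; endothelial cells (re)grow over
    ``stalk_regrowth_time``. Lumen target areas are governed by the
    lumen module."""
    for cell in mesh.cells.values():
        st = cell.state
        if cell.type.is_epithelial:
            full = final_area[cell.type]
            if st.target_area < full and np.isfinite(st.cycle_duration):
                st.target_area = min(
                    full, st.target_area + 0.5 * full / st.cycle_duration * dt
                )
        elif cell.type.is_endothelial:
            full = final_area[cell.type]
            if st.target_area < full:
                st.target_area = min(
                    full, st.target_area + full / endo.stalk_regrowth_time * dt
                )


# ----------------------------------------------------------------------
# endothelium
# ----------------------------------------------------------------------
def elongation_factor(cell: Cell, mesh: Mesh) -> float:
    """Shape anisotropy of the cell polygon, >= 1."""
    return _elong(mesh.cell_points(cell))


def stalk_divide_if_elongated(
    mesh: Mesh, params: EndothelialParams
) -> List[dict]:
    """Divide every stalk cell whose elongation factor reached the
    threshold, along its shortest axis; both daughters stay stalk cells
    and fixed-vertex anchoring is preserved."""
    events: List[dict] = []
    for cid in sorted(mesh.cells):
        cell = mesh.cells.get(cid)
        if cell is None or cell.type is not CellType.ENDO_STALK:
            continue
        if len(cell.ring) < 4:
            continue
        if mesh.cell_area(cell) < params.min_division_area:
            continue
        if elongation_factor(cell, mesh) < params.elongation_threshold:
            continue
        try:
            d1, d2 = divide_cell(mesh, cid)
        except DivisionError:
            continue
        for did in (d1, d2):
            ds = mesh.cells[did].state
            ds.age = 0.0
            ds.target_area = 0.5 * cell.state.target_area
        events.append(
            {"time": mesh.time, "cell": cid, "event": "stalk_division",
             "daughters": (d1, d2)}
        )
    return events


def add_endothelial_branch(
    mesh: Mesh,
    params: EndothelialParams,
    clock: float,
    rng: np.random.Generator,
) -> Optional[Tuple[int, int]]:
    """Insert one tip + one stalk cell at the periphery.

    The site is the epithelial boundary edge farthest from any existing
    endothelial cell (the largest unoccupied boundary gap). The tip is
    extruded outward from that edge as a quadrilateral sharing it with
    the epithelium; the stalk sits outward of the tip, standing in for
    the connection to a distant parent vessel. Returns
    ``(tip_id, stalk_id)`` or ``None`` when the clock passed the cutoff
    or no admissible site exists.
    """
    if clock >= params.branch_addition_cutoff:
        return None
    endo_centroids = [
        mesh.cell_centroid(c)
        for c in mesh.cells.values()
        if c.type.is_endothelial
    ]
    best = None
    best_d = -np.inf
    em = mesh.edge_map
    for (a, b), cids in sorted(em.items()):
        if len(cids) != 1:
            continue
        cell = mesh.cells[cids[0]]
        if not cell.type.is_epithelial:
            continue
        mid = 0.5 * (mesh.positions[a] + mesh.positions[b])
        if np.linalg.norm(mesh.positions[a] - mesh.positions[b]) < 0.25:
            continue
        d = (
            min(np.linalg.norm(mid - c) for c in endo_centroids)
            if endo_centroids
            else np.inf
        )
        if d > best_d:
            best_d = d
            best = ((a, b), cids[0])
    if best is None:
        warnings.warn("no admissible peripheral site for a new branch")
        return None
    (a, b), host = best
    # orient the edge as traversed by the host cell
    ring = mesh.cells[host].ring
    n = len(ring)
    for i in range(n):
        if ring[i] == b and ring[(i + 1) % n] == a:
            a, b = b, a
            break
    pa, pb = mesh.positions[a], mesh.positions[b]
    d = pb - pa
    ln = np.linalg.norm(d)
    nout = np.array([d[1], -d[0]]) / ln
    h = params.branch_extrusion_depth
    v_tip = mesh.add_vertices(np.array([pa + h * nout, pb + h * nout]))
    v_stalk = mesh.add_vertices(
        np.array([pa + 2 * h * nout, pb + 2 * h * nout]), fixed=True
    )
    tip = mesh.add_cell(
        [b, a, int(v_tip[0]), int(v_tip[1])],
        CellType.ENDO_TIP,
        CellState(target_area=params.branch_cell_area),
    )
    stalk = mesh.add_cell(
        [int(v_tip[1]), int(v_tip[0]), int(v_stalk[0]), int(v_stalk[1])],
        CellType.ENDO_STALK,
        CellState(target_area=params.branch_cell_area),
    )
    return tip.id, stalk.id


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------
def proliferating_fraction(
    mesh: Mesh, params: ProliferationParams, by_class: bool = False
):
    """EdU-proxy: fraction of epithelial cells within the reporting
    window of their next division."""
    counts = {CellType.EPI_PERIPHERAL: [0, 0], CellType.EPI_CENTRAL: [0, 0]}
    for cell in mesh.cells.values():
        if not cell.type.is_epithelial:
            continue
        tot = counts[cell.type]
        tot[1] += 1
        if (
            np.isfinite(cell.state.cycle_duration)
            and cell.state.cycle_duration - cell.state.age <= params.edu_window
        ):
            tot[0] += 1
    if by_class:
        return {
            t: (c[0] / c[1] if c[1] else 0.0) for t, c in counts.items()
        }
    num = sum(c[0] for c in counts.values())
    den = sum(c[1] for c in counts.values())
    return num / den if den else 0.0
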