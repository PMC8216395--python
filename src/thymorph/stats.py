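"""Summary statistics of a tissue state.

These are the quantities used for calibration and comparison with the
imaging data: per-type cell counts, the endothelial area fraction,
lumen count and areas, the proliferating-fraction proxy, and the
number of connected epithelial components ("islets") produced by
tissue fission.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Optional

import numpy as np

from .mesh import CellType, Mesh
from .populations import ProliferationParams, proliferating_fraction

__all__ = ["SummaryStats", "compute_summary_stats", "count_islets"]


@dataclass
class SummaryStats:
    time: float
    n_cells: int
    n_epithelial: int
    n_epithelial_peripheral: int
    n_epithelial_central: int
    n_endothelial: int
    n_tip: int
    n_stalk: int
    n_lumen: int
    total_area: float
    endothelial_fraction: float
    lumen_total_area: float
    lumen_mean_area: float
    lumen_present: bool
    proliferating_fraction: float
    proliferating_fraction_peripheral: float
    proliferating_fraction_central: float
    islets: int

    def as_dict(self) -> dict:
        return asdict(self)


def count_islets(mesh: Mesh) -> int:
    """Connected components of the epithelial edge-adjacency graph."""
    epi = [cid for cid, c in sorted(mesh.cells.items()) if c.type.is_epithelial]
    if not epi:
        return 0
    epi_set = set(epi)
    adj: Dict[int, set] = {cid: set() for cid in epi}
    for (a, b), cids in mesh.edge_map.items():
        if len(cids) == 2 and cids[0] in epi_set and cids[1] in epi_set:
            adj[cids[0]].add(cids[1])
            adj[cids[1]].add(cids[0])
    seen: set = set()
    comps = 0
    for cid in epi:
        if cid in seen:
            continue
        comps += 1
        stack = [cid]
        seen.add(cid)
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
    return comps


def compute_summary_stats(
    mesh: Mesh, prolif: Optional[ProliferationParams] = None
) -> SummaryStats:
    prolif = prolif or ProliferationParams()
    areas = {cid: mesh.cell_area(c) for cid, c in mesh.cells.items()}
    total = sum(areas.values())
    by_type: Dict[CellType, int] = {t: 0 for t in CellType}
    for c in mesh.cells.values():
        by_type[c.type] += 1
    endo_area = sum(
        a for cid, a in areas.items() if mesh.cells[cid].type.is_endothelial
    )
    lumen_areas = [
        a for cid, a in areas.items() if mesh.cells[cid].type is CellType.LUMEN
    ]
    frac_by = proliferating_fraction(mesh, prolif, by_class=True)
    return SummaryStats(
        time=mesh.time,
        n_cells=len(mesh.cells),
        n_epithelial=by_type[CellType.EPI_CENTRAL] + by_type[CellType.EPI_PERIPHERAL],
        n_epithelial_peripheral=by_type[CellType.EPI_PERIPHERAL],
        n_epithelial_central=by_type[CellType.EPI_CENTRAL],
        n_endothelial=by_type[CellType.ENDO_TIP] + by_type[CellType.ENDO_STALK],
        n_tip=by_type[CellType.ENDO_TIP],
        n_stalk=by_type[CellType.ENDO_STALK],
        n_lumen=by_type[CellType.LUMEN],
        total_area=total,
        endothelial_fraction=endo_area / total if total > 0 else 0.0,
        lumen_total_area=float(np.sum(lumen_areas)) if lumen_areas else 0.0,
        lumen_mean_area=float(np.mean(lumen_areas)) if lumen_areas else 0.0,
        lumen_present=bool(lumen_areas),
        proliferating_fraction=proliferating_fraction(mesh, prolif),
        proliferating_fraction_peripheral=frac_by[CellType.EPI_PERIPHERAL],
        proliferating_fraction_central=frac_by[CellType.EPI_CENTRAL],
        islets=count_islets(mesh),
    )
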