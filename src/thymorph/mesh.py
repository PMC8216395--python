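"""Tissue mesh: vertices, polygonal cells, adjacency and invariants.

The mesh is the single mutable state of the simulation. Cells are
CCW-oriented vertex rings tagged with a cell type (epithelial central or
peripheral, endothelial tip or stalk, or lumen) and a per-cell
:class:`CellState`. Interior vertices are shared by exactly three cells
(transient multicellular rosettes excepted); boundary vertices by one or
two.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .geometry import (
    DegeneratePolygonError,
    is_simple_polygon,
    polygon_area,
    polygon_centroid,
    polygon_perimeter,
)

__all__ = ["CellType", "CellState", "Cell", "Mesh", "MeshInvariantError", "check_mesh"]


class CellType(str, Enum):
    EPI_CENTRAL = "epithelial_central"
    EPI_PERIPHERAL = "epithelial_peripheral"
    ENDO_TIP = "endothelial_tip"
    ENDO_STALK = "endothelial_stalk"
    LUMEN = "lumen"

    @property
    def is_epithelial(self) -> bool:
        return self in (CellType.EPI_CENTRAL, CellType.EPI_PERIPHERAL)

    @property
    def is_endothelial(self) -> bool:
        return self in (CellType.ENDO_TIP, CellType.ENDO_STALK)


#: marker used in line-tension tables for the tissue's free boundary
BOUNDARY = "boundary"


@dataclass
class CellState:
    """Per-cell biological bookkeeping.

    age
        hours since the cell's birth (division or simulation start).
    generation
        number of divisions in the cell's lineage since t=0.
    cycle_duration
        hours between birth and the next timed division; sampled at
        birth from the location-specific cycle length.
    target_area
        the preferred area A0 entering the area-elasticity energy.
    polarity
        apico-basal polarity vector p; zero for unpolarised cells and
        always zero for endothelial and lumen cells.
    """

    age: float = 0.0
    generation: int = 0
    cycle_duration: float = np.inf
    target_area: float = 1.0
    polarity: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def copy(self) -> "CellState":
        return CellState(
            age=self.age,
            generation=self.generation,
            cycle_duration=self.cycle_duration,
            target_area=self.target_area,
            polarity=self.polarity.copy(),
        )


@dataclass
class Cell:
    id: int
    ring: List[int]
    type: CellType
    state: CellState = field(default_factory=CellState)


class MeshInvariantError(RuntimeError):
    """A topological or geometric invariant of the mesh is violated."""


class Mesh:
    """Vertex-model tissue state.

    Vertex positions live in a flat numpy array so that force
    evaluation and time stepping are fully vectorised; cells are python
    objects holding ordered vertex-id rings. Derived adjacency
    structures are cached and invalidated via a topology version
    counter that every topological edit bumps.
    """

    def __init__(self) -> None:
        self._pos = np.empty((0, 2), dtype=float)
        self._alive = np.empty(0, dtype=bool)
        self._fixed = np.empty(0, dtype=bool)
        self.cells: Dict[int, Cell] = {}
        self.time: float = 0.0
        self.topology_version: int = 0
        self.tracked_rosettes: set[int] = set()
        self._cache_version = -1
        self._edge_map: Dict[Tuple[int, int], List[int]] = {}
        self._vertex_cells: Dict[int, List[int]] = {}

    # ------------------------------------------------------------------
    # vertices
    # ------------------------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        return self._pos

    @property
    def fixed_mask(self) -> np.ndarray:
        return self._fixed

    @property
    def alive_mask(self) -> np.ndarray:
        return self._alive

    @property
    def n_vertices(self) -> int:
        return int(self._alive.sum())

    def add_vertex(self, pos, fixed: bool = False) -> int:
        vid = self._pos.shape[0]
        self._pos = np.vstack([self._pos, np.asarray(pos, float).reshape(1, 2)])
        self._alive = np.append(self._alive, True)
        self._fixed = np.append(self._fixed, fixed)
        self.bump()
        return vid

    def add_vertices(self, pos: np.ndarray, fixed: bool = False) -> np.ndarray:
        pos = np.asarray(pos, float).reshape(-1, 2)
        start = self._pos.shape[0]
        self._pos = np.vstack([self._pos, pos])
        self._alive = np.append(self._alive, np.ones(len(pos), bool))
        self._fixed = np.append(self._fixed, np.full(len(pos), fixed))
        self.bump()
        return np.arange(start, start + len(pos))

    def remove_vertex(self, vid: int) -> None:
        self._alive[vid] = False
        self.tracked_rosettes.discard(vid)
        self.bump()

    def fix_vertex(self, vid: int, fixed: bool = True) -> None:
        self._fixed[vid] = fixed

    def position(self, vid: int) -> np.ndarray:
        return self._pos[vid]

    # ------------------------------------------------------------------
    # cells
    # ------------------------------------------------------------------
    def add_cell(
        self,
        ring: Iterable[int],
        ctype: CellType,
        state: Optional[CellState] = None,
        cell_id: Optional[int] = None,
    ) -> Cell:
        if cell_id is None:
            cell_id = max(self.cells, default=-1) + 1
        cell = Cell(cell_id, list(ring), ctype, state or CellState())
        if len(cell.ring) < 3:
            raise MeshInvariantError(f"cell {cell_id}: ring shorter than 3")
        self.cells[cell_id] = cell
        self.bump()
        return cell

    def remove_cell(self, cell_id: int) -> None:
        del self.cells[cell_id]
        self.bump()

    def bump(self) -> None:
        self.topology_version += 1

    # ------------------------------------------------------------------
    # derived geometry
    # ------------------------------------------------------------------
    def cell_points(self, cell: Cell) -> np.ndarray:
        return self._pos[cell.ring]

    def cell_area(self, cell: Cell) -> float:
        ring = cell.ring
        if len(set(ring)) < 3:
            raise DegeneratePolygonError(f"cell {cell.id}: <3 distinct vertices")
        return polygon_area(self._pos[ring])

    def cell_perimeter(self, cell: Cell) -> float:
        return polygon_perimeter(self._pos[cell.ring])

    def cell_centroid(self, cell: Cell) -> np.ndarray:
        return polygon_centroid(self._pos[cell.ring])

    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells.values())

    # ------------------------------------------------------------------
    # adjacency (cached on topology version)
    # ------------------------------------------------------------------
    def _refresh_cache(self) -> None:
        if self._cache_version == self.topology_version:
            return
        edge_map: Dict[Tuple[int, int], List[int]] = {}
        vertex_cells: Dict[int, List[int]] = {}
        ring_v: List[int] = []
        ring_next: List[int] = []
        ring_cell: List[int] = []
        cell_order = sorted(self.cells)
        for ci, cid in enumerate(cell_order):
            ring = self.cells[cid].ring
            n = len(ring)
            for i in range(n):
                a, b = ring[i], ring[(i + 1) % n]
                key = (a, b) if a < b else (b, a)
                edge_map.setdefault(key, []).append(cid)
                vertex_cells.setdefault(a, []).append(cid)
                ring_v.append(a)
                ring_next.append(b)
                ring_cell.append(ci)
        neighbor_map: Dict[int, List[int]] = {cid: [] for cid in cell_order}
        cell_bedges: Dict[int, List[Tuple[int, int]]] = {
            cid: [] for cid in cell_order
        }
        for key, cids in edge_map.items():
            if len(cids) == 2:
                neighbor_map[cids[0]].append(cids[1])
                neighbor_map[cids[1]].append(cids[0])
            else:
                cell_bedges[cids[0]].append(key)
        self._edge_map = edge_map
        self._vertex_cells = vertex_cells
        self._neighbor_map = neighbor_map
        self._cell_bedges = cell_bedges
        self._boundary_edges = [e for e, cs in edge_map.items() if len(cs) == 1]
        bvs: set[int] = set()
        for a, b in self._boundary_edges:
            bvs.add(a)
            bvs.add(b)
        self._boundary_vertices = bvs
        self._cell_order = cell_order
        self._ring_v = np.asarray(ring_v, dtype=np.int64)
        self._ring_next = np.asarray(ring_next, dtype=np.int64)
        self._ring_cell = np.asarray(ring_cell, dtype=np.int64)
        self._cache_version = self.topology_version

    @property
    def edge_map(self) -> Dict[Tuple[int, int], List[int]]:
        """Undirected edge -> sorted list of adjacent cell ids."""
        self._refresh_cache()
        return self._edge_map

    @property
    def vertex_cells(self) -> Dict[int, List[int]]:
        self._refresh_cache()
        return self._vertex_cells

    @property
    def neighbor_map(self) -> Dict[int, List[int]]:
        """Cell id -> edge-sharing neighbour cell ids (cached)."""
        self._refresh_cache()
        return self._neighbor_map

    @property
    def cell_boundary_edge_map(self) -> Dict[int, List[Tuple[int, int]]]:
        """Cell id -> list of its free-boundary edges (cached)."""
        self._refresh_cache()
        return self._cell_bedges

    def geometry_table(self):
        """Vectorised per-cell geometry: ``(cell_ids, areas, centroids)``
        computed in one pass from the cached flat rings."""
        self._refresh_cache()
        pos = self._pos
        rv = pos[self._ring_v]
        rn = pos[self._ring_next]
        cross = rv[:, 0] * rn[:, 1] - rn[:, 0] * rv[:, 1]
        ncells = len(self._cell_order)
        areas = 0.5 * np.bincount(self._ring_cell, weights=cross, minlength=ncells)
        sx = np.bincount(
            self._ring_cell,
            weights=(rv[:, 0] + rn[:, 0]) * cross,
            minlength=ncells,
        )
        sy = np.bincount(
            self._ring_cell,
            weights=(rv[:, 1] + rn[:, 1]) * cross,
            minlength=ncells,
        )
        denom = np.where(np.abs(areas) < 1e-14, 1e-14, 6.0 * areas)
        centroids = np.column_stack([sx / denom, sy / denom])
        return list(self._cell_order), areas, centroids

    def edge_length(self, edge: Tuple[int, int]) -> float:
        a, b = edge
        return float(np.linalg.norm(self._pos[a] - self._pos[b]))

    def boundary_edges(self) -> List[Tuple[int, int]]:
        self._refresh_cache()
        return self._boundary_edges

    def boundary_vertices(self) -> set[int]:
        self._refresh_cache()
        return self._boundary_vertices

    def cell_neighbors(self, cell_id: int) -> List[int]:
        """Cells sharing at least one edge with ``cell_id`` (sorted, unique)."""
        ring = self.cells[cell_id].ring
        n = len(ring)
        out: set[int] = set()
        em = self.edge_map
        for i in range(n):
            a, b = ring[i], ring[(i + 1) % n]
            key = (a, b) if a < b else (b, a)
            for cid in em.get(key, ()):
                if cid != cell_id:
                    out.add(cid)
        return sorted(out)

    def cell_boundary_edges(self, cell_id: int) -> List[Tuple[int, int]]:
        ring = self.cells[cell_id].ring
        n = len(ring)
        em = self.edge_map
        out = []
        for i in range(n):
            a, b = ring[i], ring[(i + 1) % n]
            key = (a, b) if a < b else (b, a)
            if len(em[key]) == 1:
                out.append((a, b))
        return out

    def cells_of_type(self, *types: CellType) -> List[Cell]:
        return [c for cid, c in sorted(self.cells.items()) if c.type in types]

    # ------------------------------------------------------------------
    # serialisation (JSON mesh dialect)
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        vids = sorted(np.flatnonzero(self._alive).tolist())
        return {
            "time": self.time,
            "vertices": {
                str(v): {
                    "position": self._pos[v].tolist(),
                    "fixed": bool(self._fixed[v]),
                }
                for v in vids
            },
            "cells": [
                {
                    "id": c.id,
                    "ring": list(c.ring),
                    "type": c.type.value,
                    "age": c.state.age,
                    "generation": c.state.generation,
                    "cycle_duration": (
                        None if np.isinf(c.state.cycle_duration) else c.state.cycle_duration
                    ),
                    "target_area": c.state.target_area,
                    "polarity": c.state.polarity.tolist(),
                }
                for cid, c in sorted(self.cells.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mesh":
        mesh = cls()
        vids = sorted(int(k) for k in d["vertices"])
        n = max(vids) + 1 if vids else 0
        mesh._pos = np.zeros((n, 2))
        mesh._alive = np.zeros(n, bool)
        mesh._fixed = np.zeros(n, bool)
        for k, v in d["vertices"].items():
            i = int(k)
            mesh._pos[i] = v["position"]
            mesh._alive[i] = True
            mesh._fixed[i] = bool(v.get("fixed", False))
        for c in d["cells"]:
            dur = c.get("cycle_duration")
            state = CellState(
                age=c.get("age", 0.0),
                generation=c.get("generation", 0),
                cycle_duration=np.inf if dur is None else float(dur),
                target_area=c.get("target_area", 1.0),
                polarity=np.asarray(c.get("polarity", [0.0, 0.0]), float),
            )
            mesh.add_cell(c["ring"], CellType(c["type"]), state, cell_id=c["id"])
        mesh.time = d.get("time", 0.0)
        mesh.bump()
        return mesh

    # ------------------------------------------------------------------
    # construction from raw rings (used by the IC builder and tests)
    # ------------------------------------------------------------------
    @classmethod
    def from_rings(
        cls,
        rings: List[np.ndarray],
        types: Optional[List[CellType]] = None,
        snap: float = 1e-7,
    ) -> "Mesh":
        """Build a mesh from per-cell coordinate rings, welding vertices
        that coincide within ``snap``."""
        mesh = cls()
        lookup: Dict[Tuple[int, int], int] = {}
        pts: List[np.ndarray] = []

        def vid_for(p: np.ndarray) -> int:
            key = (int(round(p[0] / snap)), int(round(p[1] / snap)))
            if key in lookup:
                return lookup[key]
            vid = len(pts)
            pts.append(np.asarray(p, float))
            lookup[key] = vid
            return vid

        rows = []
        for i, ring in enumerate(rings):
            ring = np.asarray(ring, float)
            if polygon_area(ring) < 0:
                ring = ring[::-1]
            ids = []
            for p in ring:
                v = vid_for(p)
                if not ids or ids[-1] != v:
                    ids.append(v)
            if len(ids) > 1 and ids[0] == ids[-1]:
                ids.pop()
            if len(ids) < 3:
                raise MeshInvariantError(f"ring {i} degenerate after welding")
            rows.append(ids)
        mesh._pos = np.asarray(pts, float).reshape(-1, 2)
        mesh._alive = np.ones(len(pts), bool)
        mesh._fixed = np.zeros(len(pts), bool)
        for i, ids in enumerate(rows):
            ctype = types[i] if types is not None else CellType.EPI_CENTRAL
            mesh.add_cell(ids, ctype, cell_id=i)
        return mesh


# ----------------------------------------------------------------------
# invariant checking
# ----------------------------------------------------------------------
def check_mesh(
    mesh: Mesh,
    check_simple: bool = True,
    allow_rosettes: bool = False,
) -> List[str]:
    """Return a list of invariant violations (empty when the mesh is valid).

    Checks: finite positions; ring validity and positive area; interior
    vertex cell-degree exactly 3 (unless tracked as a rosette), boundary
    vertex degree 1-2; interior edges shared by exactly 2 cells with
    opposite traversal orientation; optional simple-polygon check.
    """
    errs: List[str] = []
    pos = mesh.positions
    if not np.all(np.isfinite(pos[mesh.alive_mask])):
        errs.append("non-finite vertex position")

    directed: Dict[Tuple[int, int], int] = {}
    for cid, cell in sorted(mesh.cells.items()):
        ring = cell.ring
        if len(ring) < 3:
            errs.append(f"cell {cid}: fewer than 3 vertices")
            continue
        if len(set(ring)) != len(ring):
            errs.append(f"cell {cid}: repeated vertex in ring")
            continue
        a = polygon_area(pos[ring])
        if a <= 0:
            errs.append(f"cell {cid}: non-positive area {a:.3g}")
        if check_simple and not is_simple_polygon(pos[ring]):
            errs.append(f"cell {cid}: self-intersecting polygon")
        n = len(ring)
        for i in range(n):
            key = (ring[i], ring[(i + 1) % n])
            directed[key] = directed.get(key, 0) + 1

    for (a, b), count in directed.items():
        if count > 1:
            errs.append(f"directed edge {a}->{b} used {count} times")
        rev = directed.get((b, a), 0)
        if rev > 1:
            continue
        # undirected multiplicity
        total = count + rev
        if total > 2:
            errs.append(f"edge {{{a},{b}}} shared by {total} cells")

    bvs = mesh.boundary_vertices()
    for vid, cids in mesh.vertex_cells.items():
        deg = len(cids)
        if vid in bvs:
            if deg > 2 and not (allow_rosettes or vid in mesh.tracked_rosettes):
                errs.append(f"boundary vertex {vid} has cell-degree {deg}")
        else:
            if deg != 3 and not (allow_rosettes or vid in mesh.tracked_rosettes):
                errs.append(f"interior vertex {vid} has cell-degree {deg}")

    for (a, b) in mesh.edge_map:
        if mesh.edge_length((a, b)) <= 0:
            errs.append(f"zero-length edge {{{a},{b}}}")
    return errs


def assert_valid(mesh: Mesh, **kw) -> None:
    errs = check_mesh(mesh, **kw)
    if errs:
        raise MeshInvariantError("; ".join(errs[:10]))
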