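"""Junctional rearrangements (T1/T2/T3, rosettes) and cell division.

Five topological operations keep the cell sheet contiguous and
non-intersecting while cells move, grow and divide:

* T1 (edge swap): when an edge becomes shorter than a threshold it is
  reconnected so the two cells that shared it separate and the two
  flanking cells become neighbours.
* T2 (extrusion): a triangular cell below an area threshold is removed
  and replaced by a single vertex.
* T3 (boundary merge): a boundary vertex that drifts onto another
  cell's boundary edge is inserted into that edge so cells cannot
  interpenetrate.
* rosette resolution: vertices transiently shared by more than three
  cells are split back into degree-3 vertices.
* cell division along the shortest axis through the centroid.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    point_segment_distance,
    polygon_area,
    polygon_centroid,
    segment_intersection_point,
    segments_intersect,
    shortest_axis,
)
from .mesh import Cell, CellState, CellType, Mesh, MeshInvariantError

__all__ = [
    "RearrangementThresholds",
    "apply_t1",
    "apply_t2",
    "apply_t3",
    "resolve_rosette",
    "rearrangement_sweep",
    "divide_cell",
    "DivisionError",
]


@dataclass
class RearrangementThresholds:
    """Trigger lengths/areas for the topological operations (length in
    cell diameters, area in squared cell diameters)."""

    t1_threshold: float = 0.01
    t1_new_length_factor: float = 1.5
    t2_area_threshold: float = 0.001
    t3_tolerance: float = 0.01
    max_iterations: int = 10


class DivisionError(RuntimeError):
    """Division line could not be made to cross exactly two edges."""


# ----------------------------------------------------------------------
# ring helpers
# ----------------------------------------------------------------------
def _dedupe_ring(ring: List[int]) -> List[int]:
    out: List[int] = []
    for v in ring:
        if not out or out[-1] != v:
            out.append(v)
    while len(out) > 1 and out[0] == out[-1]:
        out.pop()
    # a vertex may still appear twice non-consecutively after an edge
    # collapse (pinched ring); keep the first occurrence only
    if len(set(out)) != len(out):
        seen: set = set()
        out2: List[int] = []
        for v in out:
            if v not in seen:
                seen.add(v)
                out2.append(v)
        out = out2
    return out


def _directed_pair_cell(mesh: Mesh, a: int, b: int) -> Optional[int]:
    """Cell id whose ring traverses a -> b consecutively, if any."""
    for cid in mesh.edge_map.get((a, b) if a < b else (b, a), ()):
        ring = mesh.cells[cid].ring
        n = len(ring)
        for i in range(n):
            if ring[i] == a and ring[(i + 1) % n] == b:
                return cid
    return None


# ----------------------------------------------------------------------
# T1
# ----------------------------------------------------------------------
def apply_t1(
    mesh: Mesh,
    edge: Tuple[int, int],
    thresholds: RearrangementThresholds,
    force: bool = False,
) -> bool:
    """Perform a T1 swap on ``edge`` if it is below threshold.

    Returns True when a swap (or the boundary collapse variant)
    happened. Edges whose two endpoints are both fixed (anchored stalk
    junctions) are exempt.
    """
    a, b = edge
    key = (a, b) if a < b else (b, a)
    cids = mesh.edge_map.get(key)
    if cids is None:
        return False
    if not force and mesh.edge_length(key) >= thresholds.t1_threshold:
        return False
    if mesh.fixed_mask[a] and mesh.fixed_mask[b]:
        return False

    if len(cids) == 1:
        return _collapse_edge(mesh, a, b)

    c1 = _directed_pair_cell(mesh, a, b)
    c2 = _directed_pair_cell(mesh, b, a)
    if c1 is None or c2 is None:
        return False
    cell1, cell2 = mesh.cells[c1], mesh.cells[c2]
    if len(cell1.ring) <= 3 or len(cell2.ring) <= 3:
        return False  # triangles are handled by T2, not T1

    others_a = [c for c in mesh.vertex_cells.get(a, []) if c not in (c1, c2)]
    others_b = [c for c in mesh.vertex_cells.get(b, []) if c not in (c1, c2)]
    if len(others_a) > 1 or len(others_b) > 1:
        return False  # rosette at an endpoint; resolved separately
    da = others_a[0] if others_a else None
    db = others_b[0] if others_b else None
    if da is not None and da == db:
        # the two flanks are one cell (doubled adjacency): merge instead
        return _collapse_edge(mesh, a, b)

    # reposition: rotate the edge 90 degrees about its midpoint
    pos = mesh.positions
    m0 = 0.5 * (pos[a] + pos[b])
    uv = pos[b] - pos[a]
    ln = np.linalg.norm(uv)
    u = uv / ln if ln > 1e-14 else np.array([1.0, 0.0])
    w = np.array([u[1], -u[0]])
    l_new = thresholds.t1_new_length_factor * thresholds.t1_threshold
    if mesh.fixed_mask[a]:
        new_a, new_b = pos[a].copy(), pos[a] + l_new * w
    elif mesh.fixed_mask[b]:
        new_a, new_b = pos[b] - l_new * w, pos[b].copy()
    else:
        new_a, new_b = m0 - 0.5 * l_new * w, m0 + 0.5 * l_new * w

    # dry-run the swap: none of the four involved cells may end up
    # inverted (a T1 next to a tiny or sliver cell can flip it)
    def prospective_area(ring):
        pts = pos[ring].copy()
        for i, v in enumerate(ring):
            if v == a:
                pts[i] = new_a
            elif v == b:
                pts[i] = new_b
        return polygon_area(pts)

    r1 = [v for v in cell1.ring if v != b]
    r2 = [v for v in cell2.ring if v != a]
    trial = [r1, r2]
    if da is not None:
        rda = list(mesh.cells[da].ring)
        rda.insert(rda.index(a), b)
        trial.append(rda)
    if db is not None:
        rdb = list(mesh.cells[db].ring)
        rdb.insert(rdb.index(b), a)
        trial.append(rdb)
    if any(prospective_area(r) <= 1e-12 for r in trial):
        return False

    cell1.ring.remove(b)
    cell2.ring.remove(a)
    if da is not None:
        ring = mesh.cells[da].ring
        ring.insert(ring.index(a), b)
    if db is not None:
        ring = mesh.cells[db].ring
        ring.insert(ring.index(b), a)
    pos[a] = new_a
    pos[b] = new_b
    mesh.bump()
    return True


def _collapse_edge(mesh: Mesh, a: int, b: int) -> bool:
    """Collapse a short edge into a single vertex (boundary T1 variant,
    also the fallback for unswappable interior edges)."""
    if mesh.fixed_mask[b] and not mesh.fixed_mask[a]:
        a, b = b, a
    pos = mesh.positions
    if not mesh.fixed_mask[a]:
        pos[a] = 0.5 * (pos[a] + pos[b])
    doomed: List[int] = []
    for cid in list(mesh.vertex_cells.get(b, [])):
        cell = mesh.cells[cid]
        cell.ring = _dedupe_ring([a if v == b else v for v in cell.ring])
        if len(set(cell.ring)) < 3:
            doomed.append(cid)
    for cid in doomed:
        mesh.remove_cell(cid)
    mesh.remove_vertex(b)
    mesh.bump()
    if len(mesh.vertex_cells.get(a, [])) > 3:
        mesh.tracked_rosettes.add(a)
    return True


# ----------------------------------------------------------------------
# T2
# ----------------------------------------------------------------------
def apply_t2(
    mesh: Mesh, cell_id: int, area_threshold: float, force: bool = False
) -> bool:
    """Remove a small triangular cell, replacing it by its centroid vertex."""
    cell = mesh.cells[cell_id]
    if len(cell.ring) != 3:
        raise MeshInvariantError(
            f"T2 called on cell {cell_id} with {len(cell.ring)} vertices"
        )
    if not force and mesh.cell_area(cell) >= area_threshold:
        return False
    tri = list(cell.ring)
    # a rosette corner would wire unrelated cells onto the new vertex;
    # let rosette resolution run first and retry next sweep iteration
    if any(len(mesh.vertex_cells.get(v, ())) > 3 for v in tri):
        return False
    pts = mesh.positions[tri]
    fixed = [bool(mesh.fixed_mask[v]) for v in tri]
    if any(fixed):
        keep = tri[fixed.index(True)]
        new_pos, new_fixed = mesh.positions[keep].copy(), True
    else:
        new_pos, new_fixed = pts.mean(axis=0), False
    mesh.remove_cell(cell_id)
    vnew = mesh.add_vertex(new_pos, fixed=new_fixed)
    doomed: List[int] = []
    for cid in sorted(mesh.cells):
        c = mesh.cells[cid]
        if any(v in tri for v in c.ring):
            c.ring = _dedupe_ring([vnew if v in tri else v for v in c.ring])
            if len(set(c.ring)) < 3:
                doomed.append(cid)
    for cid in doomed:
        mesh.remove_cell(cid)
    for v in tri:
        mesh.remove_vertex(v)
    mesh.bump()
    if len(mesh.vertex_cells.get(vnew, [])) > 3:
        mesh.tracked_rosettes.add(vnew)
    return True


# ----------------------------------------------------------------------
# T3
# ----------------------------------------------------------------------
def apply_t3(
    mesh: Mesh,
    vertex: int,
    edge: Tuple[int, int],
    tolerance: float,
) -> bool:
    """Insert boundary vertex ``vertex`` into boundary ``edge`` it overlaps."""
    a, b = edge
    key = (a, b) if a < b else (b, a)
    cids = mesh.edge_map.get(key)
    if cids is None or len(cids) != 1:
        return False
    cid = cids[0]
    ring = mesh.cells[cid].ring
    if vertex in ring:
        return False
    from .geometry import point_segment_distance

    p = mesh.positions[vertex]
    dist, t = point_segment_distance(p, mesh.positions[a], mesh.positions[b])
    if dist > tolerance:
        return False
    n = len(ring)
    for i in range(n):
        x, y = ring[i], ring[(i + 1) % n]
        if {x, y} == {a, b}:
            ring.insert(i + 1, vertex)
            break
    else:
        return False
    if not mesh.fixed_mask[vertex]:
        proj = mesh.positions[a] + t * (mesh.positions[b] - mesh.positions[a])
        mesh.positions[vertex] = proj
    mesh.bump()
    if len(mesh.vertex_cells.get(vertex, [])) > 3:
        mesh.tracked_rosettes.add(vertex)
    return True


# ----------------------------------------------------------------------
# rosettes
# ----------------------------------------------------------------------
def _fan_order(mesh: Mesh, vid: int, cids: Sequence[int]) -> List[int]:
    """Cells around ``vid`` sorted by centroid angle, rotated so any
    angular gap (boundary fan) sits between last and first."""
    p = mesh.positions[vid]
    angs = []
    for cid in cids:
        c = mesh.cell_centroid(mesh.cells[cid]) - p
        angs.append(np.arctan2(c[1], c[0]))
    order = np.argsort(angs)
    sorted_cids = [cids[i] for i in order]
    sorted_angs = [angs[i] for i in order]
    k = len(sorted_cids)
    gaps = [
        (sorted_angs[(i + 1) % k] - sorted_angs[i]) % (2 * np.pi) for i in range(k)
    ]
    start = (int(np.argmax(gaps)) + 1) % k
    return sorted_cids[start:] + sorted_cids[:start]


def resolve_rosette(
    mesh: Mesh, vid: int, thresholds: RearrangementThresholds
) -> bool:
    """Split a vertex shared by >3 cells (or a boundary vertex shared by
    >2) into two vertices, peeling one cell off the fan."""
    cids = list(mesh.vertex_cells.get(vid, []))
    is_boundary = vid in mesh.boundary_vertices()
    limit = 2 if is_boundary else 3
    if len(cids) <= limit:
        mesh.tracked_rosettes.discard(vid)
        return False
    fan = _fan_order(mesh, vid, cids)
    if is_boundary:
        group_a, interfaces, group_b = [fan[0]], [fan[1]], fan[2:]
    else:
        group_a, interfaces, group_b = [fan[0]], [fan[1], fan[-1]], fan[2:-1]
    if not group_b:
        return False

    pos = mesh.positions
    ca = np.mean([mesh.cell_centroid(mesh.cells[c]) for c in group_a], axis=0)
    cb = np.mean([mesh.cell_centroid(mesh.cells[c]) for c in group_b], axis=0)
    axis = ca - cb
    nrm = np.linalg.norm(axis)
    axis = axis / nrm if nrm > 1e-12 else np.array([1.0, 0.0])
    sep = 0.5 * thresholds.t1_new_length_factor * thresholds.t1_threshold
    p0 = pos[vid].copy()
    if mesh.fixed_mask[vid]:
        # the resulting edge must still exceed the T1 trigger
        vnew = mesh.add_vertex(p0 - 2 * sep * axis, fixed=False)
    else:
        vnew = mesh.add_vertex(p0 - sep * axis, fixed=False)
        # NB: add_vertex reallocates the position array
        mesh.positions[vid] = p0 + sep * axis

    group_b_set = set(group_b)
    # decide interface insertions on the *unmodified* topology: the new
    # vertex attaches to whichever of the cell's two junction edges
    # faces the B side of the fan
    decisions = []
    for cid in interfaces:
        ring = mesh.cells[cid].ring
        i = ring.index(vid)
        y = ring[(i + 1) % len(ring)]
        ny = _directed_pair_cell(mesh, y, vid)
        decisions.append((cid, ny is not None and ny in group_b_set))
    # B cells hand the vertex over to the new one
    for cid in group_b:
        ring = mesh.cells[cid].ring
        mesh.cells[cid].ring = [vnew if v == vid else v for v in ring]
    # interface cells keep both, gaining the new short edge
    for cid, after in decisions:
        ring = mesh.cells[cid].ring
        i = ring.index(vid)
        ring.insert(i + 1 if after else i, vnew)
    mesh.bump()
    mesh.tracked_rosettes.discard(vid)
    if len(mesh.vertex_cells.get(vnew, [])) > 3:
        mesh.tracked_rosettes.add(vnew)
    return True


# ----------------------------------------------------------------------
# sweep
# ----------------------------------------------------------------------
def rearrangement_sweep(
    mesh: Mesh,
    thresholds: Optional[RearrangementThresholds] = None,
) -> Dict[str, int]:
    """Apply T1/T2/T3, rosette resolution and fold repair until no
    trigger remains.

    Deterministic: triggers are processed in ascending id order. If the
    iteration cap is hit with short edges still churning, further
    iterations collapse them outright (guaranteed progress); raises
    only if even that fails to quiesce.
    """
    thresholds = thresholds or RearrangementThresholds()
    counts = {"t1": 0, "t2": 0, "t3": 0, "rosette": 0, "fold": 0}
    for _ in range(thresholds.max_iterations):
        if not _sweep_iteration(mesh, thresholds, counts, force_collapse=False):
            return counts
    # cap hit: same passes, but short edges are collapsed outright
    for _ in range(8):
        if not _sweep_iteration(mesh, thresholds, counts, force_collapse=True):
            return counts
    if _any_trigger(mesh, thresholds):
        raise MeshInvariantError(
            f"rearrangement sweep did not converge after "
            f"{thresholds.max_iterations} iterations at t={mesh.time:.3f} h"
        )
    return counts


def _sweep_iteration(
    mesh: Mesh,
    thresholds: RearrangementThresholds,
    counts: Dict[str, int],
    force_collapse: bool,
) -> bool:
    """One full pass of every rearrangement trigger; True if changed."""
    changed = False

    # T1: short edges, ascending (a, b); vectorised trigger scan
    em = mesh.edge_map
    keys = np.array(sorted(em), dtype=np.int64).reshape(-1, 2)
    if len(keys):
        pos = mesh.positions
        lengths = np.linalg.norm(pos[keys[:, 0]] - pos[keys[:, 1]], axis=1)
        for a, b in keys[lengths < thresholds.t1_threshold]:
            key = (int(a), int(b))
            if key not in mesh.edge_map:
                continue
            if mesh.edge_length(key) >= thresholds.t1_threshold:
                continue
            if mesh.fixed_mask[a] and mesh.fixed_mask[b]:
                continue
            if not force_collapse and apply_t1(mesh, key, thresholds):
                counts["t1"] += 1
                changed = True
                continue
            # a triangular flank blocks the swap: extrude it
            handled = False
            for cid in list(mesh.edge_map.get(key, ())):
                cell = mesh.cells.get(cid)
                if (
                    cell is not None
                    and len(cell.ring) == 3
                    and cell.type is not CellType.LUMEN
                ):
                    if apply_t2(
                        mesh, cid, thresholds.t2_area_threshold, force=True
                    ):
                        counts["t2"] += 1
                        changed = True
                        handled = True
                    break
            if force_collapse and not handled and key in mesh.edge_map:
                if _collapse_edge(mesh, int(a), int(b)):
                    counts["t1"] += 1
                    changed = True

    # T2: small triangles (lumen cells are never extruded); larger
    # cells crushed below the area threshold (including inverted ones)
    # are collapsed down to a triangle first. Vectorised area scan.
    cids_list, areas, _ = mesh.geometry_table()
    small = [
        cid
        for cid, area in zip(cids_list, areas)
        if area < thresholds.t2_area_threshold
    ]
    for cid in small:
        cell = mesh.cells.get(cid)
        if cell is None or cell.type is CellType.LUMEN:
            continue
        if mesh.cell_area(cell) >= thresholds.t2_area_threshold:
            continue
        if len(cell.ring) == 3:
            if apply_t2(mesh, cid, thresholds.t2_area_threshold):
                counts["t2"] += 1
                changed = True
            elif _shrink_degenerate_cell(mesh, cid):
                changed = True
        else:
            if _shrink_degenerate_cell(mesh, cid):
                changed = True

    # T3: boundary vertex near a foreign boundary edge
    n_t3 = _t3_pass(mesh, thresholds)
    counts["t3"] += n_t3
    changed = changed or n_t3 > 0

    # redundant interior vertices (left behind by cell removal):
    # a vertex shared by exactly two cells with no boundary edge
    # splits a straight interface and is merged away
    bvs = mesh.boundary_vertices()
    for vid in sorted(mesh.vertex_cells):
        cids = mesh.vertex_cells.get(vid)
        if cids is None or len(cids) != 2 or vid in bvs:
            continue
        if mesh.fixed_mask[vid]:
            continue
        r1 = mesh.cells[cids[0]].ring
        r2 = mesh.cells[cids[1]].ring
        if len(r1) > 3 and len(r2) > 3:
            r1.remove(vid)
            r2.remove(vid)
            mesh.remove_vertex(vid)
            mesh.bump()
            changed = True

    # rosettes
    bvs = mesh.boundary_vertices()
    for vid in sorted(mesh.vertex_cells):
        cids = mesh.vertex_cells.get(vid)
        if cids is None:
            continue
        limit = 2 if vid in bvs else 3
        if len(cids) > limit:
            if resolve_rosette(mesh, vid, thresholds):
                counts["rosette"] += 1
                changed = True
                bvs = mesh.boundary_vertices()

    # folds last, so the iteration never ends on a fresh crossing
    n_folds = repair_folds(mesh, thresholds)
    counts["fold"] += n_folds
    changed = changed or n_folds > 0
    return changed


def _shrink_degenerate_cell(mesh: Mesh, cid: int) -> bool:
    """Collapse a crushed cell down to a triangle (shortest collapsible
    edge first) and extrude it."""
    changed = False
    for _ in range(16):
        cell = mesh.cells.get(cid)
        if cell is None:
            return changed
        if len(cell.ring) == 3:
            if apply_t2(mesh, cid, 0.0, force=True):
                return True
            # T2 blocked (rosette corner): merge two corners instead,
            # which dissolves the triangle via the collapse machinery
            ring = cell.ring
            cands = []
            for i in range(3):
                a, b = ring[i], ring[(i + 1) % 3]
                if mesh.fixed_mask[a] and mesh.fixed_mask[b]:
                    continue
                cands.append((mesh.edge_length((a, b)), a, b))
            if not cands:
                return changed
            _, a, b = min(cands)
            return _collapse_edge(mesh, a, b) or changed
        ring = cell.ring
        n = len(ring)
        candidates = []
        for i in range(n):
            a, b = ring[i], ring[(i + 1) % n]
            if mesh.fixed_mask[a] and mesh.fixed_mask[b]:
                continue
            candidates.append((mesh.edge_length((a, b)), a, b))
        if not candidates:
            return changed
        _, a, b = min(candidates)
        if not _collapse_edge(mesh, a, b):
            return changed
        changed = True
    return changed


def _any_trigger(mesh: Mesh, thresholds: RearrangementThresholds) -> bool:
    keys = np.array(sorted(mesh.edge_map), dtype=np.int64).reshape(-1, 2)
    if not len(keys):
        return False
    pos = mesh.positions
    lengths = np.linalg.norm(pos[keys[:, 0]] - pos[keys[:, 1]], axis=1)
    both_fixed = mesh.fixed_mask[keys[:, 0]] & mesh.fixed_mask[keys[:, 1]]
    return bool(np.any((lengths < thresholds.t1_threshold) & ~both_fixed))


def _t3_pass(mesh: Mesh, thresholds: RearrangementThresholds) -> int:
    bedges = mesh.boundary_edges()
    if not bedges:
        return 0
    bverts = sorted(mesh.boundary_vertices())
    pos = mesh.positions
    tree = cKDTree(pos[bverts])
    count = 0
    vc = mesh.vertex_cells
    for a, b in bedges:
        if (a, b) if a < b else (b, a) not in mesh.edge_map:
            continue
        mid = 0.5 * (pos[a] + pos[b])
        r = 0.5 * np.linalg.norm(pos[a] - pos[b]) + thresholds.t3_tolerance
        for j in tree.query_ball_point(mid, r):
            v = bverts[j]
            if v in (a, b):
                continue
            cids = mesh.edge_map.get((a, b) if a < b else (b, a))
            if not cids:
                break
            if v in mesh.cells[cids[0]].ring:
                continue
            # only merge genuinely foreign contacts, not ring neighbours
            if set(vc.get(v, ())) & set(cids):
                continue
            if apply_t3(mesh, v, (a, b), thresholds.t3_tolerance):
                count += 1
                break
    return count


# ----------------------------------------------------------------------
# division
# ----------------------------------------------------------------------
def resolve_interpenetrations(mesh: Mesh, pad: float = 3e-3) -> int:
    """Project foreign vertices out of every cell they have entered.

    A fast-advancing interface (a chemotactic tip, a growing lumen, a
    crowded junction) can sweep past a non-incident vertex before any
    edge becomes short enough to trigger a T1; the vertex then sits
    strictly inside a cell it does not belong to and the surrounding
    rings fold. This contact pass moves each such vertex to the nearest
    point of the offended cell's boundary plus ``pad`` outward, after
    which the ordinary rearrangements can restore the topology.
    Returns the number of vertices moved.
    """
    alive = np.flatnonzero(mesh.alive_mask & ~mesh.fixed_mask)
    if not len(alive) or not mesh.cells:
        return 0
    pts = mesh.positions[alive]
    tree = cKDTree(pts)
    moved = 0
    pos = mesh.positions
    cell_ids, _, centroids = mesh.geometry_table()
    rv = mesh._ring_v
    rc = mesh._ring_cell
    dist = np.linalg.norm(pos[rv] - centroids[rc], axis=1)
    radii = np.zeros(len(cell_ids))
    np.maximum.at(radii, rc, dist)
    all_cand = tree.query_ball_point(centroids, radii + 1e-9)
    for i, cid in enumerate(cell_ids):
        cell = mesh.cells[cid]
        ring_set = set(cell.ring)
        if len(ring_set) < 3:
            continue
        cand = [j for j in all_cand[i] if int(alive[j]) not in ring_set]
        if not cand:
            continue
        ring_pts = pos[cell.ring]
        xy = pos[alive[cand]]
        inside = _points_in_ring(ring_pts, xy)
        if not inside.any():
            continue
        for j, isin in zip(cand, inside):
            if not isin:
                continue
            vid = int(alive[j])
            q, out_dir = _nearest_boundary_point(ring_pts, pos[vid])
            nrm = np.linalg.norm(out_dir)
            if nrm < 1e-12:
                continue
            mesh.positions[vid] = q + pad * out_dir / nrm
            moved += 1
    return moved


def _points_in_ring(ring_pts: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Vectorised crossing-number point-in-polygon test."""
    x1 = ring_pts[:, 0]
    y1 = ring_pts[:, 1]
    x2 = np.concatenate([x1[1:], x1[:1]])
    y2 = np.concatenate([y1[1:], y1[:1]])
    px = xy[:, 0][:, None]
    py = xy[:, 1][:, None]
    cond = (y1[None, :] > py) != (y2[None, :] > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1[None, :] + (py - y1[None, :]) * (x2 - x1)[None, :] / (
            y2 - y1
        )[None, :]
    crossings = np.sum(cond & (px < xint), axis=1)
    return (crossings % 2) == 1


def _nearest_boundary_point(ring_pts: np.ndarray, p: np.ndarray):
    """Closest point on the ring boundary to ``p`` and the outward
    direction from ``p`` toward it."""
    a = ring_pts
    b = np.vstack([ring_pts[1:], ring_pts[:1]])
    ab = b - a
    denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-30)
    t = np.clip(np.einsum("ij,ij->i", p[None, :] - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - p, axis=1)
    k = int(np.argmin(d))
    q = proj[k]
    return q, q - p


_PAIR_CACHE: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}


def _nonadjacent_pairs(n: int):
    """Index pairs (i, j) of non-adjacent edges of an n-ring (cached)."""
    if n not in _PAIR_CACHE:
        ii, jj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (j + 1) % n == i or (i + 1) % n == j:
                    continue
                ii.append(i)
                jj.append(j)
        _PAIR_CACHE[n] = (np.asarray(ii), np.asarray(jj))
    return _PAIR_CACHE[n]


def _count_crossings(pts: np.ndarray) -> int:
    """Vectorised count of properly crossing non-adjacent edge pairs."""
    n = len(pts)
    if n < 4:
        return 0
    ii, jj = _nonadjacent_pairs(n)
    nxt = np.arange(1, n + 1) % n
    p1 = pts[ii]
    p2 = pts[nxt[ii]]
    q1 = pts[jj]
    q2 = pts[nxt[jj]]

    def orient(a, b, c):
        return (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (
            b[:, 1] - a[:, 1]
        ) * (c[:, 0] - a[:, 0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    eps = 1e-12
    return int(np.sum((d1 * d2 < -eps) & (d3 * d4 < -eps)))


def _ring_has_crossing(pts: np.ndarray) -> bool:
    return _count_crossings(pts) > 0


def _crossing_cells(mesh: Mesh) -> List[int]:
    """Ids of cells whose rings contain a proper crossing, found by one
    vectorised orientation computation over all non-adjacent edge pairs
    of every ring (pair index arrays cached on the topology version)."""
    cache = getattr(mesh, "_fold_pair_cache", None)
    if cache is None or cache[0] != mesh.topology_version:
        p1l, p2l, q1l, q2l, cell_l = [], [], [], [], []
        for cid in sorted(mesh.cells):
            ring = mesh.cells[cid].ring
            n = len(ring)
            if n < 4:
                continue
            ii, jj = _nonadjacent_pairs(n)
            arr = np.asarray(ring)
            nxt = np.concatenate([arr[1:], arr[:1]])
            p1l.append(arr[ii])
            p2l.append(nxt[ii])
            q1l.append(arr[jj])
            q2l.append(nxt[jj])
            cell_l.append(np.full(len(ii), cid))
        if p1l:
            cache = (
                mesh.topology_version,
                (
                    np.concatenate(p1l),
                    np.concatenate(p2l),
                    np.concatenate(q1l),
                    np.concatenate(q2l),
                    np.concatenate(cell_l),
                ),
            )
        else:
            cache = (mesh.topology_version, None)
        mesh._fold_pair_cache = cache
    if cache[1] is None:
        return []
    p1i, p2i, q1i, q2i, cells = cache[1]
    pos = mesh.positions
    p1 = pos[p1i]
    p2 = pos[p2i]
    q1 = pos[q1i]
    q2 = pos[q2i]

    def orient(a, b, c):
        return (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (
            b[:, 1] - a[:, 1]
        ) * (c[:, 0] - a[:, 0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    eps = 1e-12
    hit = (d1 * d2 < -eps) & (d3 * d4 < -eps)
    if not hit.any():
        return []
    return sorted(set(int(c) for c in cells[hit]))


def _intercalate_vertex_edge(
    mesh: Mesh, v: int, edge: Tuple[int, int]
) -> bool:
    """Interior vertex-edge intercalation.

    Vertex ``v`` has reached (or crossed) a non-incident edge. The
    vertex is merged into the edge: it is inserted into the rings of
    the cells sharing the edge, and any cell that already contains both
    ``v`` and the edge is pinched into two lobes meeting at ``v`` (the
    advancing interface has cut it in two). The resulting high-degree
    junction is handed to rosette resolution. Returns True on change.
    """
    a, b = edge
    key = (a, b) if a < b else (b, a)
    cids = mesh.edge_map.get(key)
    if not cids or mesh.fixed_mask[v]:
        return False
    pos = mesh.positions
    d, t = point_segment_distance(pos[v], pos[a], pos[b])
    proj = pos[a] + t * (pos[b] - pos[a])

    # dry run: the operation must be applicable to *every* cell sharing
    # the edge, or to none — a partial application desynchronises the
    # directed-edge structure
    plans = []
    for cid in list(cids):
        cell = mesh.cells.get(cid)
        if cell is None:
            return False
        ring = cell.ring
        n = len(ring)
        idx = None
        for i in range(n):
            if {ring[i], ring[(i + 1) % n]} == {a, b}:
                idx = i
                break
        if idx is None:
            return False
        if v in ring:
            ring2 = ring[: idx + 1] + [v] + ring[idx + 1 :]
            p = ring2.index(v)
            r = len(ring2) - 1 - ring2[::-1].index(v)
            lobe1 = _dedupe_ring(ring2[p:r])
            lobe2 = _dedupe_ring(ring2[r:] + ring2[:p])
            if len(set(lobe1)) < 3 or len(set(lobe2)) < 3:
                return False
            # both lobes must stay positively oriented; an inverted
            # lobe means the crossing is too deep to pinch cleanly
            a1 = polygon_area(pos[lobe1])
            a2 = polygon_area(pos[lobe2])
            if a1 <= 1e-9 or a2 <= 1e-9:
                return False
            plans.append(("pinch", cid, lobe1, lobe2, a1, a2))
        else:
            plans.append(("insert", cid, idx))

    for plan in plans:
        if plan[0] == "pinch":
            _, cid, lobe1, lobe2, a1, a2 = plan
            cell = mesh.cells[cid]
            state = cell.state
            ctype = cell.type
            tot = max(a1 + a2, 1e-12)
            mesh.remove_cell(cid)
            c1 = mesh.add_cell(lobe1, ctype, state.copy())
            c2 = mesh.add_cell(lobe2, ctype, state.copy())
            c1.state.target_area = state.target_area * a1 / tot
            c2.state.target_area = state.target_area * a2 / tot
        else:
            _, cid, idx = plan
            mesh.cells[cid].ring.insert(idx + 1, v)
            mesh.bump()
    mesh.positions[v] = proj
    mesh.bump()
    bvs = mesh.boundary_vertices()
    if len(mesh.vertex_cells.get(v, [])) > (2 if v in bvs else 3):
        mesh.tracked_rosettes.add(v)
    return True


def repair_folds(
    mesh: Mesh,
    thresholds: Optional[RearrangementThresholds] = None,
    pad: float = 2e-3,
    candidates=None,
) -> int:
    """Untangle self-intersecting cell rings.

    When a motile interface (an advancing tip, a growing lumen) slides
    past a junction vertex of a squeezed neighbour, two edges of that
    neighbour's ring cross without any edge having become short: a
    state no T1/T2/T3 trigger sees. The natural resolution is the T1
    that lets the interface advance past the junction: the ring edge
    joining the offending vertex to the crossed edge is swapped
    regardless of its length. Where no such edge exists the vertex is
    merged into the crossed edge (vertex-edge intercalation, pinching a
    cut cell in two) or, failing that, placed just to whichever side of
    the crossed edge reduces the ring's crossing count.

    ``candidates`` limits the scan (default: every cell; a vectorised
    crossing pre-test keeps the quiet case cheap). Returns the number
    of repairs performed.
    """
    thresholds = thresholds or RearrangementThresholds()
    if candidates is None:
        candidates = _crossing_cells(mesh)
    moved = 0
    pos = mesh.positions
    for cid in sorted(candidates):
        cell = mesh.cells.get(cid)
        if cell is None or len(set(cell.ring)) < 4:
            continue
        if not _ring_has_crossing(pos[cell.ring]):
            continue
        for _ in range(4):  # a ring may need a couple of repairs
            cell = mesh.cells.get(cid)
            if cell is None or len(set(cell.ring)) < 4:
                break
            ring = cell.ring
            n = len(ring)
            pts = pos[ring]
            crossing = None
            for i in range(n):
                a1, a2 = pts[i], pts[(i + 1) % n]
                for j in range(i + 1, n):
                    if j == i or (j + 1) % n == i or (i + 1) % n == j:
                        continue
                    if segments_intersect(a1, a2, pts[j], pts[(j + 1) % n]):
                        crossing = (i, j)
                        break
                if crossing:
                    break
            if crossing is None:
                break
            i, j = crossing
            edge_i = (ring[i], ring[(i + 1) % n])
            edge_j = (ring[j], ring[(j + 1) % n])
            # X-twist: both edges cross mid-span, no endpoint near the
            # opposite edge; reconnecting one of them untangles it
            min_d = min(
                point_segment_distance(pos[v], pos[ea], pos[eb])[0]
                for v, (ea, eb) in (
                    (edge_i[0], edge_j),
                    (edge_i[1], edge_j),
                    (edge_j[0], edge_i),
                    (edge_j[1], edge_i),
                )
            )
            if min_d > 0.05:
                done = False
                for e in sorted(
                    (edge_i, edge_j),
                    key=lambda e: float(np.linalg.norm(pos[e[0]] - pos[e[1]])),
                ):
                    key = (e[0], e[1]) if e[0] < e[1] else (e[1], e[0])
                    if key in mesh.edge_map and apply_t1(
                        mesh, key, thresholds, force=True
                    ):
                        moved += 1
                        done = True
                        break
                if done:
                    continue
            # offender: of the four endpoints, the one closest to the
            # opposite edge (it just slipped across it)
            best = None
            for v, (ea, eb) in (
                (edge_i[0], edge_j),
                (edge_i[1], edge_j),
                (edge_j[0], edge_i),
                (edge_j[1], edge_i),
            ):
                if mesh.fixed_mask[v]:
                    continue
                d, t = point_segment_distance(pos[v], pos[ea], pos[eb])
                if best is None or d < best[0]:
                    best = (d, v, ea, eb, t)
            if best is None:
                break
            _, v, ea, eb, t = best
            # preferred: swap the existing ring edge from the offender
            # to the nearer endpoint of the crossed edge
            em = mesh.edge_map
            t1_done = False
            for other in sorted(
                (ea, eb),
                key=lambda e: float(np.linalg.norm(pos[v] - pos[e])),
            ):
                key = (v, other) if v < other else (other, v)
                if key in em and apply_t1(mesh, key, thresholds, force=True):
                    moved += 1
                    t1_done = True
                    break
            if t1_done:
                continue
            if _intercalate_vertex_edge(mesh, v, (ea, eb)):
                moved += 1
                continue
            # last resort: positional untangling. For each unfixed
            # endpoint of the crossing pair, try placing it just on
            # either side of the opposite edge and keep the first
            # placement that reduces the ring's crossing count.
            before = _count_crossings(pos[cell.ring])
            repaired = False
            trials = sorted(
                (
                    (edge_i[0], edge_j),
                    (edge_i[1], edge_j),
                    (edge_j[0], edge_i),
                    (edge_j[1], edge_i),
                ),
                key=lambda ve: point_segment_distance(
                    pos[ve[0]], pos[ve[1][0]], pos[ve[1][1]]
                )[0],
            )
            for vv, (ta, tb) in trials:
                if mesh.fixed_mask[vv]:
                    continue
                dd, tt = point_segment_distance(pos[vv], pos[ta], pos[tb])
                proj = pos[ta] + tt * (pos[tb] - pos[ta])
                d_edge = pos[tb] - pos[ta]
                nvec = np.array([-d_edge[1], d_edge[0]])
                nn = np.linalg.norm(nvec)
                if nn < 1e-12:
                    continue
                nvec /= nn
                saved = pos[vv].copy()
                for side in (1.0, -1.0):
                    pos[vv] = proj + side * pad * nvec
                    if _count_crossings(pos[cell.ring]) < before:
                        repaired = True
                        moved += 1
                        break
                    pos[vv] = saved
                if repaired:
                    break
            if not repaired:
                # escalation: reconnect or merge one crossing edge
                for e in sorted(
                    (edge_i, edge_j),
                    key=lambda e: float(
                        np.linalg.norm(pos[e[0]] - pos[e[1]])
                    ),
                ):
                    key = (e[0], e[1]) if e[0] < e[1] else (e[1], e[0])
                    if key not in mesh.edge_map:
                        continue
                    if apply_t1(mesh, key, thresholds, force=True):
                        repaired = True
                        moved += 1
                        break
                    if not (
                        mesh.fixed_mask[e[0]] and mesh.fixed_mask[e[1]]
                    ) and _collapse_edge(mesh, e[0], e[1]):
                        repaired = True
                        moved += 1
                        break
                if not repaired:
                    break
    return moved


def divide_cell(
    mesh: Mesh,
    cell_id: int,
    axis: Optional[np.ndarray] = None,
) -> Tuple[int, int]:
    """Divide a cell along ``axis`` (default: its shortest axis) through
    the centroid. Returns the two daughter cell ids; daughters inherit a
    copy of the mother's state (the caller adjusts ages/areas/types).

    New junction vertices are fixed only when created on an edge whose
    two endpoints are both fixed, preserving endothelial anchoring.
    """
    cell = mesh.cells[cell_id]
    ring = list(cell.ring)
    pts = mesh.positions[ring]
    centroid = polygon_centroid(pts)
    if axis is None:
        axis = shortest_axis(pts)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)

    span = 4.0 * float(np.max(np.linalg.norm(pts - centroid, axis=1))) + 1e-9
    hits = None
    for jitter in (0.0, 0.07, -0.07, 0.15, -0.15, 0.35, -0.35):
        ca, sa = np.cos(jitter), np.sin(jitter)
        rot = np.array([[ca, -sa], [sa, ca]])
        d = rot @ axis
        p1 = centroid - span * d
        p2 = centroid + span * d
        found = []
        n = len(ring)
        ok = True
        for i in range(n):
            q1 = pts[i]
            q2 = pts[(i + 1) % n]
            ipt = segment_intersection_point(p1, p2, q1, q2)
            if ipt is None:
                continue
            t_edge = np.linalg.norm(ipt - q1) / max(
                np.linalg.norm(q2 - q1), 1e-30
            )
            if t_edge < 1e-6 or t_edge > 1 - 1e-6:
                ok = False  # grazes a vertex; jitter and retry
                break
            found.append((i, ipt))
        if not ok:
            continue
        if len(found) == 2:
            hits = found
            break
        if len(found) > 2 and len(found) % 2 == 0:
            # non-convex: take the two crossings bracketing the centroid
            s = [(np.dot(ipt - centroid, d), i, ipt) for i, ipt in found]
            neg = [h for h in s if h[0] < 0]
            pos_h = [h for h in s if h[0] >= 0]
            if neg and pos_h:
                lo = max(neg, key=lambda h: h[0])
                hi = min(pos_h, key=lambda h: h[0])
                hits = sorted(
                    [(lo[1], lo[2]), (hi[1], hi[2])], key=lambda h: h[0]
                )
                break
    if hits is None:
        raise DivisionError(
            f"cell {cell_id}: division line does not cross two edges"
        )

    (i1, pt1), (i2, pt2) = sorted(hits, key=lambda h: h[0])

    def edge_fixed(i):
        return bool(
            mesh.fixed_mask[ring[i]] and mesh.fixed_mask[ring[(i + 1) % len(ring)]]
        )

    v1 = mesh.add_vertex(pt1, fixed=edge_fixed(i1))
    v2 = mesh.add_vertex(pt2, fixed=edge_fixed(i2))

    n = len(ring)
    ring_a = ring[i1 + 1 : i2 + 1] + [v2, v1]
    ring_b = ring[i2 + 1 :] + ring[: i1 + 1] + [v1, v2]

    # insert the junction vertices into the neighbouring cells' rings
    for (idx, vnew) in ((i1, v1), (i2, v2)):
        a, b = ring[idx], ring[(idx + 1) % n]
        nb = _directed_pair_cell(mesh, b, a)
        if nb is not None and nb != cell_id:
            r = mesh.cells[nb].ring
            r.insert(r.index(a), vnew)

    state = cell.state
    ctype = cell.type
    mesh.remove_cell(cell_id)
    d1 = mesh.add_cell(ring_a, ctype, state.copy())
    d2 = mesh.add_cell(ring_b, ctype, state.copy())
    for d in (d1, d2):
        if polygon_area(mesh.positions[d.ring]) <= 0:
            raise DivisionError(f"daughter of {cell_id} has non-positive area")
    mesh.bump()
    return d1.id, d2.id
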