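"""Junctional rearrangements and division: textbook topologies and
geometry-oracle checks."""
import numpy as np
import pytest

from thymorph.geometry import is_simple_polygon, polygon_area
from thymorph.mesh import CellType, Mesh, MeshInvariantError, check_mesh
from thymorph.rearrange import (
    DivisionError,
    RearrangementThresholds,
    apply_t1,
    apply_t2,
    apply_t3,
    divide_cell,
    rearrangement_sweep,
    resolve_rosette,
)

from conftest import make_single_cell, random_voronoi_mesh

THRESH = RearrangementThresholds()


def four_cell_t1_mesh(edge_len=0.005):
    """Left/right cells share a short vertical edge; top/bottom flank it."""
    h = edge_len / 2
    v0, v1 = (0, h), (0, -h)
    left = [(-0.5, -0.5), v1, v0, (-0.5, 0.5), (-1, 0)]
    right = [(0.5, -0.5), (1, 0), (0.5, 0.5), v0, v1]
    top = [v0, (0.5, 0.5), (0, 1), (-0.5, 0.5)]
    bottom = [v1, (-0.5, -0.5), (0, -1), (0.5, -0.5)]
    return Mesh.from_rings(
        [np.array(r, float) for r in (left, right, top, bottom)],
        [CellType.EPI_CENTRAL] * 4,
    )


def adjacency_pairs(mesh):
    return {
        frozenset(cids) for cids in mesh.edge_map.values() if len(cids) == 2
    }


def test_t1_swaps_neighbour_relations():
    mesh = four_cell_t1_mesh()
    assert check_mesh(mesh) == []
    before = adjacency_pairs(mesh)
    assert frozenset({0, 1}) in before and frozenset({2, 3}) not in before
    key = min(
        (k for k, cs in mesh.edge_map.items() if len(cs) == 2 and set(cs) == {0, 1}),
        key=lambda k: mesh.edge_length(k),
    )
    assert apply_t1(mesh, key, THRESH)
    after = adjacency_pairs(mesh)
    assert frozenset({0, 1}) not in after and frozenset({2, 3}) in after
    assert len(mesh.cells) == 4
    assert check_mesh(mesh) == []
    # the reconnected edge is opened to the prescribed length
    new_key = next(k for k, cs in mesh.edge_map.items() if set(cs) == {2, 3})
    assert mesh.edge_length(new_key) == pytest.approx(
        THRESH.t1_new_length_factor * THRESH.t1_threshold
    )


def test_t1_noop_above_threshold():
    mesh = four_cell_t1_mesh(edge_len=0.5)
    key = next(k for k, cs in mesh.edge_map.items() if set(cs) == {0, 1})
    assert not apply_t1(mesh, key, THRESH)


def small_triangle_mesh(r_in=0.01):
    ang = np.pi / 2 + np.arange(3) * 2 * np.pi / 3
    t = np.column_stack([r_in * np.cos(ang), r_in * np.sin(ang)])
    b = np.column_stack([2 * np.cos(ang), 2 * np.sin(ang)])
    rings = [t]
    for k in range(3):
        j = (k + 1) % 3
        rings.append(np.array([t[j], t[k], b[k], b[j]]))
    return Mesh.from_rings(rings, [CellType.EPI_CENTRAL] * 4)


def test_t2_removes_small_triangle_and_conserves_area():
    mesh = small_triangle_mesh()
    assert check_mesh(mesh) == []
    tri_area = mesh.cell_area(mesh.cells[0])
    total_before = mesh.total_area()
    nv_before = mesh.n_vertices
    neighbour_sizes = {cid: len(mesh.cells[cid].ring) for cid in (1, 2, 3)}
    assert apply_t2(mesh, 0, area_threshold=0.01)
    assert 0 not in mesh.cells
    assert mesh.n_vertices == nv_before - 2
    for cid, n in neighbour_sizes.items():
        assert len(mesh.cells[cid].ring) == n - 1
    # the interior triangle's area is absorbed exactly by its neighbours
    assert mesh.total_area() == pytest.approx(total_before, abs=1e-12)
    assert tri_area > 0
    assert check_mesh(mesh) == []


def test_t2_noop_above_threshold():
    mesh = small_triangle_mesh(r_in=0.5)
    assert not apply_t2(mesh, 0, area_threshold=0.001)
    assert 0 in mesh.cells


def test_t2_rejects_non_triangle(unit_square_mesh):
    with pytest.raises(MeshInvariantError):
        apply_t2(unit_square_mesh, 0, area_threshold=1.0)


def facing_cells_mesh(gap=1e-4):
    a = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)
    b = np.array([(1 + gap, 0.3), (2, 0.2), (2, 0.8), (1 + gap, 0.7)], float)
    return Mesh.from_rings([a, b], [CellType.EPI_CENTRAL] * 2)


def test_t3_merges_overlapping_boundary_vertex():
    mesh = facing_cells_mesh()
    # cell 1's left-bottom vertex sits 1e-4 off cell 0's right edge
    v = mesh.cells[1].ring[0]
    edge = next(
        k
        for k, cs in mesh.edge_map.items()
        if cs == [0]
        and np.allclose(mesh.positions[list(k)][:, 0], 1.0)
    )
    assert apply_t3(mesh, v, edge, tolerance=1e-3)
    assert v in mesh.cells[0].ring  # edge split in two by the vertex
    assert len(mesh.cells[0].ring) == 5
    # no boundary segments intersect afterwards
    from thymorph.geometry import segments_intersect

    bedges = mesh.boundary_edges()
    for i, (p, q) in enumerate(bedges):
        for (r, s) in bedges[i + 1 :]:
            assert not segments_intersect(
                mesh.positions[p],
                mesh.positions[q],
                mesh.positions[r],
                mesh.positions[s],
            )


def test_t3_noop_beyond_tolerance():
    mesh = facing_cells_mesh(gap=0.05)
    v = mesh.cells[1].ring[0]
    edge = next(k for k, cs in mesh.edge_map.items() if cs == [0])
    assert not apply_t3(mesh, v, edge, tolerance=1e-3)


def quadrant_rosette_mesh():
    """Four unit quads meeting at the origin (degree-4 interior vertex)."""
    q = [
        [(0, 0), (1, 0), (1, 1), (0, 1)],
        [(0, 0), (0, 1), (-1, 1), (-1, 0)],
        [(0, 0), (-1, 0), (-1, -1), (0, -1)],
        [(0, 0), (0, -1), (1, -1), (1, 0)],
    ]
    return Mesh.from_rings(
        [np.array(r, float) for r in q], [CellType.EPI_CENTRAL] * 4
    )


def test_rosette_resolved_to_degree_three():
    mesh = quadrant_rosette_mesh()
    centre = next(
        v for v, cs in mesh.vertex_cells.items() if len(cs) == 4
    )
    assert resolve_rosette(mesh, centre, THRESH)
    assert check_mesh(mesh) == []
    assert max(len(cs) for cs in mesh.vertex_cells.values()) == 3


def test_sweep_identity_on_quiet_mesh(small_voronoi_mesh):
    before = {cid: list(c.ring) for cid, c in small_voronoi_mesh.cells.items()}
    counts = rearrangement_sweep(small_voronoi_mesh, THRESH)
    assert all(v == 0 for v in counts.values())
    assert {cid: list(c.ring) for cid, c in small_voronoi_mesh.cells.items()} == before


def test_sweep_fixes_single_short_edge():
    mesh = four_cell_t1_mesh(edge_len=0.005)
    counts = rearrangement_sweep(mesh, THRESH)
    assert counts["t1"] == 1
    assert check_mesh(mesh) == []


def test_sweeps_with_relaxation_restore_invariants_on_perturbed_mesh():
    """Noisy vertex positions relax back to a clean tissue when sweeps
    are interleaved with mechanical relaxation, as in the simulator."""
    from thymorph.energy import ForceEvaluator, euler_step

    from conftest import uniform_params

    mesh = random_voronoi_mesh(5, n=24)
    rng = np.random.default_rng(1)
    mesh.positions[mesh.alive_mask] += rng.normal(
        0, 0.04, (mesh.n_vertices, 2)
    )
    params = uniform_params(K=1.0, Gamma=0.04, Lambda=0.1, A0=1.0)
    ev = ForceEvaluator(mesh, params)
    for _ in range(40):
        for _ in range(25):
            ev.ensure_fresh()
            euler_step(mesh, ev.forces(), 0.001)
        rearrangement_sweep(mesh, THRESH)
    for cell in mesh.cells.values():
        assert is_simple_polygon(mesh.positions[cell.ring])
    assert check_mesh(mesh) == []


# ----------------------------------------------------------------------
# division
# ----------------------------------------------------------------------
def test_divide_rectangle_into_equal_halves():
    mesh = make_single_cell([(0, 0), (2, 0), (2, 1), (0, 1)])
    d1, d2 = divide_cell(mesh, 0)
    a1, a2 = mesh.cell_area(mesh.cells[d1]), mesh.cell_area(mesh.cells[d2])
    assert a1 == pytest.approx(1.0, abs=1e-12)
    assert a2 == pytest.approx(1.0, abs=1e-12)
    # the dividing line is vertical (the shortest axis)
    new_vids = sorted(set(mesh.cells[d1].ring) & set(mesh.cells[d2].ring))
    xs = mesh.positions[new_vids][:, 0]
    assert np.allclose(xs, 1.0, atol=1e-9)


def test_divide_square_tie_break_equal_halves():
    mesh = make_single_cell([(0, 0), (1, 0), (1, 1), (0, 1)])
    d1, d2 = divide_cell(mesh, 0)
    assert mesh.cell_area(mesh.cells[d1]) == pytest.approx(0.5, abs=1e-12)
    assert mesh.cell_area(mesh.cells[d2]) == pytest.approx(0.5, abs=1e-12)


def test_division_conserves_area_on_random_convex_cells():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(4, 9)
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        if np.min(np.diff(ang)) < 0.05:
            continue
        pts = np.column_stack(
            [np.cos(ang), np.sin(ang)]
        ) * rng.uniform(0.6, 1.4, (n, 1))
        if polygon_area(pts) <= 0.05:
            continue
        mesh = make_single_cell(pts)
        mother = mesh.cell_area(mesh.cells[0])
        d1, d2 = divide_cell(mesh, 0)
        assert (
            mesh.cell_area(mesh.cells[d1]) + mesh.cell_area(mesh.cells[d2])
            == pytest.approx(mother, abs=1e-12)
        )


def test_division_updates_neighbour_rings(two_cell_mesh):
    d1, d2 = divide_cell(two_cell_mesh, 0)
    assert check_mesh(two_cell_mesh) == []
    assert len(two_cell_mesh.cells) == 3


def test_division_increments_cell_count(small_voronoi_mesh):
    n0 = len(small_voronoi_mesh.cells)
    divide_cell(small_voronoi_mesh, sorted(small_voronoi_mesh.cells)[0])
    assert len(small_voronoi_mesh.cells) == n0 + 1
    assert check_mesh(small_voronoi_mesh) == []
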