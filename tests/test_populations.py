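"""Cell-type system: classification, cycles, stalk shape-division and
branch addition."""
import numpy as np
import pytest

from thymorph.mesh import CellState, CellType, Mesh, check_mesh
from thymorph.populations import (
    EndothelialParams,
    ProliferationParams,
    add_endothelial_branch,
    advance_cycles_and_divide,
    classify_peripherality,
    cycle_duration_at_birth,
    elongation_factor,
    proliferating_fraction,
    stalk_divide_if_elongated,
)

from conftest import make_single_cell, random_voronoi_mesh, small_synthetic_ic

NO_JITTER = ProliferationParams(cycle_jitter=0.0, generation_factor=1.0)


def test_honeycomb_flower_classification(honeycomb_flower):
    labels = classify_peripherality(honeycomb_flower)
    counts = {t: sum(1 for v in labels.values() if v is t) for t in set(labels.values())}
    assert counts[CellType.EPI_PERIPHERAL] == 6
    assert counts[CellType.EPI_CENTRAL] == 1


def test_two_cell_mesh_all_peripheral(two_cell_mesh):
    labels = classify_peripherality(two_cell_mesh)
    assert all(v is CellType.EPI_PERIPHERAL for v in labels.values())


def test_classification_matches_brute_force_scan():
    mesh = random_voronoi_mesh(9, n=30)
    labels = classify_peripherality(mesh)
    # brute force: count adjacent cells per edge directly from rings
    for cid, cell in mesh.cells.items():
        ring = cell.ring
        has_free_edge = False
        for i in range(len(ring)):
            a, b = ring[i], ring[(i + 1) % len(ring)]
            sharers = [
                other
                for ocid, other in mesh.cells.items()
                if ocid != cid
                and any(
                    other.ring[j] == b
                    and other.ring[(j + 1) % len(other.ring)] == a
                    for j in range(len(other.ring))
                )
            ]
            if not sharers:
                has_free_edge = True
        expected = (
            CellType.EPI_PERIPHERAL if has_free_edge else CellType.EPI_CENTRAL
        )
        assert labels[cid] is expected


def test_classification_extends_to_endothelial_contact(two_cell_mesh):
    """An epithelial cell walled in by endothelium still counts as
    peripheral under the extended (vessel = ECM contact) definition."""
    mesh = random_voronoi_mesh(13, n=30)
    labels = classify_peripherality(mesh)
    central = [c for c, t in labels.items() if t is CellType.EPI_CENTRAL]
    target = central[0]
    nbr = mesh.neighbor_map[target][0]
    mesh.cells[nbr].type = CellType.ENDO_TIP
    mesh.bump()
    labels = classify_peripherality(mesh)
    assert labels[target] is CellType.EPI_PERIPHERAL
    labels = classify_peripherality(mesh, endothelial_contact_counts=False)
    assert labels[target] is CellType.EPI_CENTRAL


@pytest.mark.parametrize(
    "ctype, gen, g, expected",
    [
        (CellType.EPI_PERIPHERAL, 0, 1.0, 11.0 + 20.0 / 60.0),
        (CellType.EPI_CENTRAL, 0, 1.0, 31.0 + 52.0 / 60.0),
        (CellType.EPI_PERIPHERAL, 2, 1.2, (11.0 + 20.0 / 60.0) * 1.44),
    ],
)
def test_cycle_duration_at_birth(ctype, gen, g, expected):
    params = ProliferationParams(cycle_jitter=0.0, generation_factor=g)
    assert cycle_duration_at_birth(ctype, gen, params) == pytest.approx(expected)


def test_cycle_duration_rejects_non_epithelial():
    with pytest.raises(ValueError):
        cycle_duration_at_birth(CellType.ENDO_TIP, 0, NO_JITTER)


def test_cell_divides_when_age_crosses_duration(two_cell_mesh):
    for c in two_cell_mesh.cells.values():
        c.state.cycle_duration = 1.0
        c.state.age = 0.9995
    events = advance_cycles_and_divide(two_cell_mesh, NO_JITTER, dt=0.001)
    assert len(events) == 2
    assert len(two_cell_mesh.cells) == 4
    for c in two_cell_mesh.cells.values():
        assert c.state.age == 0.0
        assert c.state.generation == 1


def test_tip_cells_never_divide(two_cell_mesh):
    for c in two_cell_mesh.cells.values():
        c.type = CellType.ENDO_TIP
        c.state.age = 100.0
        c.state.cycle_duration = 1.0
    events = advance_cycles_and_divide(two_cell_mesh, NO_JITTER, dt=0.01)
    assert events == []
    assert len(two_cell_mesh.cells) == 2


def test_founder_population_doubles_once():
    """n founders with equal duration and g = 1 are exactly 2n cells
    just after one cycle, and none has divided twice."""
    mesh = random_voronoi_mesh(21, n=30)
    classify_peripherality(mesh)
    for c in mesh.cells.values():
        c.state.cycle_duration = 11.4
        c.state.age = np.random.default_rng(c.id).uniform(0, 1e-6)
    n0 = len(mesh.cells)
    events = []
    for _ in range(24):  # 12 h in 0.5 h event steps
        events += advance_cycles_and_divide(mesh, NO_JITTER, dt=0.5)
        for c in mesh.cells.values():  # freeze daughters' clocks mid-test
            if c.state.generation == 1:
                c.state.cycle_duration = np.inf
    assert len(mesh.cells) == 2 * n0
    assert len(events) == n0


def test_elongation_factor_shapes(unit_square_mesh):
    assert elongation_factor(
        next(iter(unit_square_mesh.cells.values())), unit_square_mesh
    ) == pytest.approx(1.0)
    rect = make_single_cell([(0, 0), (2, 0), (2, 1), (0, 1)])
    assert elongation_factor(
        next(iter(rect.cells.values())), rect
    ) == pytest.approx(2.0)


def test_stalk_divides_when_stretched():
    mesh = make_single_cell(
        [(0, 0), (3, 0), (3, 1), (0, 1)], ctype=CellType.ENDO_STALK
    )
    cell = next(iter(mesh.cells.values()))
    cell.state.target_area = 3.0
    params = EndothelialParams(elongation_threshold=2.0)
    mother_elong = elongation_factor(cell, mesh)
    events = stalk_divide_if_elongated(mesh, params)
    assert len(events) == 1
    assert len(mesh.cells) == 2
    for c in mesh.cells.values():
        assert c.type is CellType.ENDO_STALK
        assert elongation_factor(c, mesh) < mother_elong


def test_round_stalk_does_not_divide():
    mesh = make_single_cell(
        [(0, 0), (1, 0), (1, 1), (0, 1)], ctype=CellType.ENDO_STALK
    )
    next(iter(mesh.cells.values())).state.target_area = 1.0
    events = stalk_divide_if_elongated(
        mesh, EndothelialParams(elongation_threshold=2.0)
    )
    assert events == []


def test_branch_addition_respects_cutoff():
    ic = small_synthetic_ic(3)
    params = EndothelialParams(branch_addition_cutoff=24.0)
    rng = np.random.default_rng(0)
    assert add_endothelial_branch(ic.mesh, params, clock=30.0, rng=rng) is None


def test_branch_addition_inserts_valid_tip_stalk_pair():
    ic = small_synthetic_ic(4)
    mesh = ic.mesh
    n0 = len(mesh.cells)
    params = EndothelialParams()
    out = add_endothelial_branch(mesh, params, clock=1.0, rng=np.random.default_rng(0))
    assert out is not None
    tip_id, stalk_id = out
    assert mesh.cells[tip_id].type is CellType.ENDO_TIP
    assert mesh.cells[stalk_id].type is CellType.ENDO_STALK
    assert len(mesh.cells) == n0 + 2
    assert check_mesh(mesh) == []
    # the stalk's outer vertices are anchored
    assert any(mesh.fixed_mask[v] for v in mesh.cells[stalk_id].ring)


def test_proliferating_fraction_counts_cells_near_division(two_cell_mesh):
    cells = list(two_cell_mesh.cells.values())
    cells[0].state.cycle_duration = 10.0
    cells[0].state.age = 9.8  # inside the 0.5 h window
    cells[1].state.cycle_duration = 10.0
    cells[1].state.age = 1.0
    assert proliferating_fraction(
        two_cell_mesh, ProliferationParams()
    ) == pytest.approx(0.5)
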