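"""Runner, configuration round trip, summary statistics and snapshots."""
import numpy as np
import pandas as pd
import pytest

from thymorph.config import RunConfig, load_config, save_config
from thymorph.ic import InitialCondition
from thymorph.mesh import CellState, CellType, Mesh, check_mesh
from thymorph.simulate import Simulation, run
from thymorph.stats import compute_summary_stats, count_islets

from conftest import small_synthetic_ic


def quick_config(**kw) -> RunConfig:
    base = dict(duration=0.5, dt=0.002, seed=3, n_epithelial=60)
    base.update(kw)
    cfg = RunConfig(**base)
    cfg.ic.n_branches = 2
    cfg.ic.max_endo_fraction = 0.06
    return cfg


def test_config_yaml_round_trip(tmp_path):
    cfg = quick_config()
    p1 = tmp_path / "a.yaml"
    p2 = tmp_path / "b.yaml"
    save_config(cfg, p1)
    loaded = load_config(p1)
    save_config(loaded, p2)
    assert p1.read_text() == p2.read_text()
    assert loaded.to_dict() == cfg.to_dict()


def test_zero_duration_returns_ic_stats():
    cfg = quick_config(duration=0.0)
    res = run(cfg)
    assert len(res.events) == 0
    assert res.stats.iloc[-1]["time"] == 0.0
    assert res.stats.iloc[-1]["n_lumen"] == 0


def test_all_modules_off_is_pure_relaxation():
    cfg = quick_config(
        chemotaxis_enabled=False,
        polarity_enabled=False,
        proliferation_enabled=False,
        branch_addition_enabled=False,
        corridors_enabled=False,
    )
    sim = Simulation(cfg)
    energies = [sim.evaluator.energy()]
    for _ in range(200):
        sim.step()
        sim.evaluator.ensure_fresh()
        energies.append(sim.evaluator.energy())
    assert np.all(np.diff(energies) <= 1e-9)
    assert len(sim.events) == 0


def test_single_step_preserves_invariants():
    sim = Simulation(quick_config())
    sim.step()
    assert check_mesh(sim.mesh) == []


def test_identical_seed_identical_trajectory():
    r1 = run(quick_config(duration=0.3))
    r2 = run(quick_config(duration=0.3))
    pd.testing.assert_frame_equal(r1.stats, r2.stats)
    assert r1.events == r2.events
    assert np.array_equal(
        r1.mesh.positions[r1.mesh.alive_mask],
        r2.mesh.positions[r2.mesh.alive_mask],
    )


def test_different_seed_different_trajectory():
    r1 = run(quick_config(duration=0.3, seed=1))
    r2 = run(quick_config(duration=0.3, seed=2))
    assert not r1.stats.equals(r2.stats)


# ----------------------------------------------------------------------
# statistics
# ----------------------------------------------------------------------
def grid_mesh(nx, ny, types=None):
    rings = []
    for j in range(ny):
        for i in range(nx):
            rings.append(
                np.array(
                    [(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)], float
                )
            )
    return Mesh.from_rings(
        rings, types or [CellType.EPI_CENTRAL] * (nx * ny)
    )


def test_endothelial_fraction_arithmetic():
    types = [CellType.EPI_CENTRAL] * 49 + [CellType.ENDO_TIP]
    mesh = grid_mesh(10, 5, types)
    s = compute_summary_stats(mesh)
    assert s.total_area == pytest.approx(50.0)
    assert s.endothelial_fraction == pytest.approx(0.02)


def test_no_lumen_reported_as_zero_with_flag():
    mesh = grid_mesh(3, 3)
    s = compute_summary_stats(mesh)
    assert s.n_lumen == 0
    assert s.lumen_mean_area == 0.0
    assert not s.lumen_present


def test_islets_counted_by_component_search():
    """A row of five cells whose middle cell is a lumen splits the
    epithelium into two islets."""
    types = [CellType.EPI_CENTRAL] * 5
    types[2] = CellType.LUMEN
    mesh = grid_mesh(5, 1, types)
    assert count_islets(mesh) == 2
    # brute-force check: the two fragments are {0,1} and {3,4}
    s = compute_summary_stats(mesh)
    assert s.islets == 2
    assert s.n_lumen == 1


def test_islet_count_one_for_connected_tissue():
    assert count_islets(grid_mesh(4, 3)) == 1


# ----------------------------------------------------------------------
# snapshots
# ----------------------------------------------------------------------
def test_snapshot_json_round_trip(tmp_path):
    ic = small_synthetic_ic(8)
    from thymorph.snapshots import read_snapshot_json, write_snapshot_json

    path = tmp_path / "snap.json"
    write_snapshot_json(path, ic.mesh)
    mesh2, _ = read_snapshot_json(path)
    assert check_mesh(mesh2) == []
    assert len(mesh2.cells) == len(ic.mesh.cells)
    for cid, cell in ic.mesh.cells.items():
        other = mesh2.cells[cid]
        assert other.ring == cell.ring
        assert other.type is cell.type
        assert np.allclose(
            mesh2.positions[other.ring], ic.mesh.positions[cell.ring]
        )
        assert other.state.age == pytest.approx(cell.state.age)


def test_vtk_writer_emits_valid_polydata(tmp_path):
    ic = small_synthetic_ic(8)
    from thymorph.snapshots import write_vtk

    path = tmp_path / "snap.vtk"
    write_vtk(path, ic.mesh)
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert "DATASET POLYDATA" in text
    npoints = int(next(l for l in text if l.startswith("POINTS")).split()[1])
    assert npoints == ic.mesh.n_vertices
    poly_line = next(l for l in text if l.startswith("POLYGONS"))
    assert int(poly_line.split()[1]) == len(ic.mesh.cells)
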