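"""Shared fixtures: small hand-built meshes and random tissue generators."""
from __future__ import annotations

import numpy as np
import pytest

from thymorph.energy import EnergyParameters
from thymorph.ic import SyntheticICParams, build_voronoi_ic, synthesize_e13_ic
from thymorph.mesh import BOUNDARY, CellState, CellType, Mesh


def make_single_cell(points, ctype=CellType.EPI_CENTRAL, a0=1.0) -> Mesh:
    mesh = Mesh.from_rings([np.asarray(points, float)], [ctype])
    next(iter(mesh.cells.values())).state.target_area = a0
    return mesh


def uniform_params(
    K=1.0, Gamma=0.0, Lambda=0.0, A0=1.0
) -> EnergyParameters:
    """Same mechanics for every cell type and every edge pair."""
    p = EnergyParameters(
        K={t: K for t in CellType},
        Gamma={t: Gamma for t in CellType},
        A0_init={t: A0 for t in CellType},
    )
    names = [t.value for t in CellType] + [BOUNDARY]
    for a in names:
        for b in names:
            p.set_lambda(a, b, Lambda)
    return p


@pytest.fixture
def unit_square_mesh() -> Mesh:
    return make_single_cell([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def two_cell_mesh() -> Mesh:
    """Two unit squares sharing a vertical edge."""
    return Mesh.from_rings(
        [
            np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float),
            np.array([(1, 0), (2, 0), (2, 1), (1, 1)], float),
        ],
        [CellType.EPI_CENTRAL, CellType.EPI_CENTRAL],
    )


def hex_ring(centre, r=1.0, phase=0.0) -> np.ndarray:
    ang = phase + np.pi / 6 + np.arange(6) * np.pi / 3
    return np.column_stack(
        [centre[0] + r * np.cos(ang), centre[1] + r * np.sin(ang)]
    )


@pytest.fixture
def honeycomb_flower() -> Mesh:
    """Seven regular hexagons: one centre cell surrounded by six."""
    s = np.sqrt(3.0)
    centres = [(0.0, 0.0)] + [
        (s * np.cos(k * np.pi / 3), s * np.sin(k * np.pi / 3)) for k in range(6)
    ]
    rings = [hex_ring(c) for c in centres]
    return Mesh.from_rings(rings, [CellType.EPI_CENTRAL] * 7)


def random_voronoi_mesh(seed: int, n: int = 30) -> Mesh:
    """Clipped Voronoi tissue of ``n`` cells in a square, mildly relaxed
    seed layout (minimum-distance rejection) so no degenerate slivers."""
    rng = np.random.default_rng(seed)
    side = np.sqrt(float(n))
    pts = []
    while len(pts) < n:
        p = rng.uniform(0.35, side - 0.35, 2)
        if not pts or np.linalg.norm(np.asarray(pts) - p, axis=1).min() > 0.55:
            pts.append(p)
    boundary = np.array([(0, 0), (side, 0), (side, side), (0, side)], float)
    return build_voronoi_ic(np.asarray(pts), boundary, rescale=False)


@pytest.fixture
def small_voronoi_mesh() -> Mesh:
    return random_voronoi_mesh(0, n=24)


def small_synthetic_ic(seed: int, n: int = 60):
    """Synthetic tissue small enough for scenario tests (2 branches so
    the endothelial-fraction constraint stays satisfiable)."""
    return synthesize_e13_ic(
        n,
        rng=np.random.default_rng(seed),
        params=SyntheticICParams(n_branches=2, max_endo_fraction=0.06),
    )
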