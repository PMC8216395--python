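"""Initial-condition construction.

Two routes produce a starting tissue:

* an image-derived route: a table of cell bounding boxes exported by an
  image-analysis platform (one row per detected cell, with a class
  label) plus a closed polygon delimiting the area of analysis. Box
  centres act as Voronoi seeds; the tessellation is clipped by the
  polygon and becomes the vertex mesh.
* a fully synthetic route emulating an E13.5 mouse thyroid
  cross-section: a compact blob of a few hundred epithelial cells with
  blue-noise spacing, and four endothelial tip+stalk pairs parked at
  the periphery occupying under 2% of the tissue area.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely.geometry as sg
from scipy.spatial import Voronoi

from .mesh import CellState, CellType, Mesh
from .populations import ProliferationParams, classify_peripherality, cycle_duration_at_birth

__all__ = [
    "SeedTable",
    "InitialCondition",
    "centres_from_boxes",
    "build_voronoi_ic",
    "synthesize_e13_ic",
    "SyntheticICParams",
]


@dataclass
class InitialCondition:
    """A ready-to-simulate mesh plus the manually designated initial
    endothelial tip and stalk cell ids."""

    mesh: Mesh
    tip_ids: List[int] = field(default_factory=list)
    stalk_ids: List[int] = field(default_factory=list)


# ----------------------------------------------------------------------
# seed tables (bounding-box exports)
# ----------------------------------------------------------------------
SEED_COLUMNS = ["xmin", "ymin", "xmax", "ymax", "class"]


def read_seed_table(path) -> pd.DataFrame:
    """Read the bounding-box CSV dialect: header
    ``xmin,ymin,xmax,ymax,class``, image-pixel coordinates with y
    increasing downward (flipped to y-up at import)."""
    df = pd.read_csv(path)
    missing = [c for c in SEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"seed table missing columns {missing}")
    df = df.copy()
    ymax = float(df[["ymin", "ymax"]].to_numpy().max())
    df["ymin"], df["ymax"] = ymax - df["ymax"], ymax - df["ymin"]
    return df


class SeedTable:
    """Thin wrapper validating a bounding-box table."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SeedTable":
        return cls(read_seed_table(path))


def centres_from_boxes(table) -> List[Tuple[np.ndarray, str]]:
    """Box centres with class labels, preserving row order; degenerate
    boxes are rejected with a warning."""
    df = table.df if isinstance(table, SeedTable) else table
    out: List[Tuple[np.ndarray, str]] = []
    for i, row in df.iterrows():
        if not (row["xmax"] > row["xmin"] and row["ymax"] > row["ymin"]):
            warnings.warn(f"seed row {i}: degenerate box rejected")
            continue
        centre = np.array(
            [0.5 * (row["xmin"] + row["xmax"]), 0.5 * (row["ymin"] + row["ymax"])]
        )
        out.append((centre, str(row["class"])))
    return out


# ----------------------------------------------------------------------
# clipped Voronoi tessellation
# ----------------------------------------------------------------------
def _finite_voronoi_regions(vor: Voronoi, radius: float):
    """Close the unbounded Voronoi regions by extending their infinite
    ridges out to ``radius`` before polygon clipping."""
    centre = vor.points.mean(axis=0)
    ridge_dir = {}
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            continue
        finite = v2 if v1 < 0 else v1
        t = vor.points[p2] - vor.points[p1]
        t = t / np.linalg.norm(t)
        n = np.array([-t[1], t[0]])
        mid = vor.points[[p1, p2]].mean(axis=0)
        direction = np.sign(np.dot(mid - centre, n)) * n
        far = vor.vertices[finite] + direction * radius
        ridge_dir[(p1, p2)] = (finite, far)
        ridge_dir[(p2, p1)] = (finite, far)

    regions = []
    for p, reg_idx in enumerate(vor.point_region):
        verts = vor.regions[reg_idx]
        if -1 not in verts:
            regions.append(vor.vertices[verts])
            continue
        pts = []
        for v in verts:
            if v >= 0:
                pts.append(vor.vertices[v])
        # collect this point's two infinite-ridge far points
        far_pts = [
            far
            for (p1, p2), (fin, far) in ridge_dir.items()
            if p1 == p
        ]
        pts.extend(far_pts)
        pts = np.asarray(pts)
        c = pts.mean(axis=0)
        ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
        regions.append(pts[np.argsort(ang)])
    return regions


def build_voronoi_ic(
    seeds: Sequence,
    boundary: Sequence,
    classes: Optional[Sequence[str]] = None,
    rescale: bool = True,
) -> Mesh:
    """Clipped Voronoi tessellation of ``seeds`` inside the closed
    ``boundary`` polygon, returned as a vertex mesh.

    Seeds outside the boundary are rejected with a warning. When
    ``rescale`` is set, coordinates are scaled so that the median
    epithelial cell area is 1 (the model's unit cell). Cell types map
    from the class labels: ``epithelial`` -> central (peripherality is
    reclassified after construction), ``endothelial`` -> stalk (tips
    are designated manually afterwards).
    """
    seeds = np.asarray([np.asarray(s, float) for s in seeds])
    if classes is None:
        classes = ["epithelial"] * len(seeds)
    classes = list(classes)
    poly = sg.Polygon(np.asarray(boundary, float))
    if not poly.is_valid:
        raise ValueError("boundary polygon is not simple")

    keep = [i for i, s in enumerate(seeds) if poly.contains(sg.Point(s))]
    if len(keep) < len(seeds):
        warnings.warn(f"{len(seeds) - len(keep)} seed(s) outside boundary rejected")
    seeds = seeds[keep]
    classes = [classes[i] for i in keep]
    if len(seeds) < 3:
        raise ValueError("need at least 3 seeds inside the boundary")
    if np.linalg.matrix_rank(seeds - seeds.mean(axis=0)) < 2:
        raise ValueError("seeds are collinear")

    span = float(np.ptp(seeds, axis=0).max() + np.sqrt(poly.area)) * 4 + 1.0
    vor = Voronoi(seeds)
    regions = _finite_voronoi_regions(vor, span)

    rings, types, kept_seed_idx = [], [], []
    for i, reg in enumerate(regions):
        if len(reg) < 3:
            continue
        clipped = sg.Polygon(reg).buffer(0).intersection(poly)
        if clipped.is_empty:
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        if clipped.geom_type != "Polygon" or clipped.area <= 0:
            continue
        ring = np.asarray(
            sg.polygon.orient(clipped, 1.0).exterior.coords
        )[:-1]
        rings.append(ring)
        types.append(
            CellType.ENDO_STALK
            if classes[i] == "endothelial"
            else CellType.EPI_CENTRAL
        )
        kept_seed_idx.append(i)
    if len(rings) < 3:
        raise ValueError("fewer than 3 cells survive clipping")

    if rescale:
        epi_areas = [
            abs(_ring_area(r))
            for r, t in zip(rings, types)
            if t is CellType.EPI_CENTRAL
        ]
        scale = 1.0 / np.sqrt(np.median(epi_areas)) if epi_areas else 1.0
        rings = [r * scale for r in rings]

    typical = np.sqrt(np.median([abs(_ring_area(r)) for r in rings]))
    mesh = Mesh.from_rings(rings, types, snap=max(1e-6 * typical, 1e-9))
    for cell in mesh.cells.values():
        cell.state.target_area = mesh.cell_area(cell)
    return mesh


def _ring_area(r: np.ndarray) -> float:
    x, y = r[:, 0], r[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ----------------------------------------------------------------------
# synthetic E13.5-like generator
# ----------------------------------------------------------------------
@dataclass
class SyntheticICParams:
    """Shape and composition of the synthetic E13.5-like section.

    The defaults emulate the starting tissue used throughout: ~200
    epithelial cells in a compact, gently lobed blob, with 4
    endothelial tip+stalk pairs parked at the periphery and a total
    endothelial area fraction below 2%.
    """

    n_branches: int = 4
    blob_wobble: float = 0.07  # relative radial modulation of the blob outline
    spacing_factor: float = 0.78  # blue-noise exclusion radius vs mean spacing
    stalk_depth: float = 0.22  # stalk seed depth below boundary, in spacings
    tip_depth: float = 0.58  # tip seed depth below boundary, in spacings
    endo_clearance: float = 0.40  # epithelial seeds closer than this are dropped
    flank_offset: float = 0.55  # lateral offset of the flanking epithelial seeds
    max_endo_fraction: float = 0.02
    random_age: bool = True


def _blob_polygon(rng: np.random.Generator, radius: float, wobble: float):
    theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    r = np.ones_like(theta)
    for k in (2, 3, 4):
        r += wobble * rng.uniform(0.3, 1.0) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    pts = radius * np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return pts


def _blue_noise(
    rng: np.random.Generator, poly: sg.Polygon, n: int, r_min: float
) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    accepted: List[np.ndarray] = []
    attempts = 0
    cap = 400 * n
    while len(accepted) < n and attempts < cap:
        attempts += 1
        p = np.array(
            [rng.uniform(minx, maxx), rng.uniform(miny, maxy)]
        )
        if not poly.contains(sg.Point(p)):
            continue
        if accepted:
            d = np.linalg.norm(np.asarray(accepted) - p, axis=1)
            if d.min() < r_min:
                continue
        accepted.append(p)
    if len(accepted) < n:
        raise ValueError(
            f"could only place {len(accepted)}/{n} blue-noise seeds; "
            "reduce spacing_factor or n"
        )
    return np.asarray(accepted)


def synthesize_e13_ic(
    n_epithelial: int = 200,
    rng: Optional[np.random.Generator] = None,
    params: Optional[SyntheticICParams] = None,
    prolif: Optional[ProliferationParams] = None,
) -> InitialCondition:
    """Generate a synthetic E13.5-like initial condition.

    Epithelial seeds are blue-noise sampled inside a smooth blob; at
    ``n_branches`` well-separated peripheral sites a stalk seed is
    placed just under the outline with a tip seed slightly deeper, so
    the clipped Voronoi cells of the endothelium form small peripheral
    wedges. Epithelial ages are randomised so divisions desynchronise.
    """
    if n_epithelial < 20:
        raise ValueError("n_epithelial must be at least 20")
    rng = rng or np.random.default_rng(0)
    params = params or SyntheticICParams()
    prolif = prolif or ProliferationParams()

    radius = np.sqrt(n_epithelial / np.pi)  # unit mean cell area, pre-rescale
    outline = _blob_polygon(rng, radius, params.blob_wobble)
    poly = sg.Polygon(outline)
    spacing = np.sqrt(poly.area / n_epithelial)
    epi_seeds = _blue_noise(rng, poly, n_epithelial, params.spacing_factor * spacing)

    # endothelial branch sites, roughly evenly spread around the outline
    base = rng.uniform(0, 2 * np.pi)
    site_angles = base + np.arange(params.n_branches) * 2 * np.pi / max(
        params.n_branches, 1
    ) + rng.uniform(-0.25, 0.25, params.n_branches)
    ring = sg.LinearRing(outline)
    endo_seeds, endo_roles, flank_seeds = [], [], []
    for ang in site_angles:
        probe = sg.LineString(
            [(0, 0), (3 * radius * np.cos(ang), 3 * radius * np.sin(ang))]
        )
        hit = probe.intersection(ring)
        if hit.is_empty:
            continue
        if hit.geom_type != "Point":
            hit = list(hit.geoms)[0]
        bp = np.array([hit.x, hit.y])
        inward = -bp / np.linalg.norm(bp)
        lateral = np.array([-inward[1], inward[0]])
        endo_seeds.append(bp + params.stalk_depth * spacing * inward)
        endo_roles.append("stalk")
        endo_seeds.append(bp + params.tip_depth * spacing * inward)
        endo_roles.append("tip")
        # flanking epithelial seeds bound the endothelial wedge laterally
        for side in (-1.0, 1.0):
            flank_seeds.append(
                bp
                + 0.45 * spacing * inward
                + side * params.flank_offset * spacing * lateral
            )
    endo_seeds = np.asarray(endo_seeds)

    # drop epithelial seeds crowding the endothelial pairs
    d = np.linalg.norm(
        epi_seeds[:, None, :] - endo_seeds[None, :, :], axis=2
    ).min(axis=1)
    epi_seeds = epi_seeds[d > params.endo_clearance * spacing]
    keep_flanks = [
        f for f in flank_seeds if poly.contains(sg.Point(f))
    ]
    if keep_flanks:
        epi_seeds = np.vstack([epi_seeds, np.asarray(keep_flanks)])

    seeds = np.vstack([epi_seeds, endo_seeds])
    classes = ["epithelial"] * len(epi_seeds) + ["endothelial"] * len(endo_seeds)
    mesh = build_voronoi_ic(seeds, outline, classes)

    # designate tips: endothelial cells were created in seed order
    endo_cells = mesh.cells_of_type(CellType.ENDO_STALK)
    # order of construction == seed order, so alternate stalk/tip
    tip_ids, stalk_ids = [], []
    for cell, role in zip(endo_cells, endo_roles):
        if role == "tip":
            cell.type = CellType.ENDO_TIP
            tip_ids.append(cell.id)
        else:
            stalk_ids.append(cell.id)
    mesh.bump()

    classify_peripherality(mesh)
    for cell in mesh.cells.values():
        st = cell.state
        st.target_area = mesh.cell_area(cell)
        if cell.type.is_epithelial:
            st.cycle_duration = cycle_duration_at_birth(
                cell.type, 0, prolif, rng
            )
            if params.random_age:
                st.age = float(rng.uniform(0.0, st.cycle_duration))

    endo_area = sum(
        mesh.cell_area(c)
        for c in mesh.cells.values()
        if c.type.is_endothelial
    )
    frac = endo_area / mesh.total_area()
    if frac >= params.max_endo_fraction:
        raise ValueError(
            f"endothelial area fraction {frac:.3f} >= "
            f"{params.max_endo_fraction}; increase n_epithelial"
        )
    return InitialCondition(mesh, tip_ids=tip_ids, stalk_ids=stalk_ids)
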