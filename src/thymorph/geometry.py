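"""Low-level polygon geometry for the vertex model.

All routines operate on ``(n, 2)`` float arrays holding a polygon's
vertices in counter-clockwise (CCW) order. Lengths are expressed in
nominal cell diameters, the model's unit of length.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "second_moment_tensor",
    "principal_axes",
    "elongation_factor",
    "shortest_axis",
    "is_simple_polygon",
    "segments_intersect",
    "segment_intersection_point",
    "point_segment_distance",
]


class DegeneratePolygonError(ValueError):
    """Raised when a polygon has fewer than 3 distinct vertices or zero area."""


def _as_ring(pts) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegeneratePolygonError(
            f"polygon needs >=3 2D vertices, got shape {pts.shape}"
        )
    return pts


def polygon_area(pts) -> float:
    """Signed shoelace area; positive for CCW rings."""
    pts = _as_ring(pts)
    x, y = pts[:, 0], pts[:, 1]
    a = float(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))
    a += float(x[-1] * y[0] - x[0] * y[-1])
    return 0.5 * a


def polygon_perimeter(pts) -> float:
    pts = _as_ring(pts)
    d = pts[1:] - pts[:-1]
    seg = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
    last = pts[0] - pts[-1]
    return float(seg.sum() + np.sqrt(last[0] ** 2 + last[1] ** 2))


def polygon_centroid(pts) -> np.ndarray:
    """Area centroid (not the vertex mean)."""
    pts = _as_ring(pts)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.concatenate([x[1:], x[:1]]), np.concatenate([y[1:], y[:1]])
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-14:
        raise DegeneratePolygonError("zero-area polygon has no centroid")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def second_moment_tensor(pts) -> np.ndarray:
    """Area second-moment (covariance) tensor about the centroid.

    Returns the symmetric 2x2 matrix with entries ``Ixx = ∫ x'^2 dA``,
    ``Iyy = ∫ y'^2 dA`` and ``Ixy = ∫ x'y' dA`` where primes are
    centroid-relative coordinates. For a w×h axis-aligned rectangle this
    gives ``diag(w^3 h / 12, w h^3 / 12)``.
    """
    pts = _as_ring(pts)
    c = polygon_centroid(pts)
    p = pts - c
    q = np.roll(p, -1, axis=0)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    ixx = np.sum(cross * (p[:, 0] ** 2 + p[:, 0] * q[:, 0] + q[:, 0] ** 2)) / 12.0
    iyy = np.sum(cross * (p[:, 1] ** 2 + p[:, 1] * q[:, 1] + q[:, 1] ** 2)) / 12.0
    ixy = (
        np.sum(
            cross
            * (
                2.0 * p[:, 0] * p[:, 1]
                + p[:, 0] * q[:, 1]
                + q[:, 0] * p[:, 1]
                + 2.0 * q[:, 0] * q[:, 1]
            )
        )
        / 24.0
    )
    return np.array([[ixx, ixy], [ixy, iyy]])


def principal_axes(pts):
    """Eigen-decomposition of the second-moment tensor.

    Returns ``(eigvals, eigvecs)`` sorted descending so that
    ``eigvecs[:, 0]`` spans the long (major) axis and ``eigvecs[:, 1]``
    the short (minor) axis.
    """
    t = second_moment_tensor(pts)
    vals, vecs = np.linalg.eigh(t)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def elongation_factor(pts) -> float:
    """Shape anisotropy sqrt(lambda_major / lambda_minor); 1 for shapes
    with three-fold or higher symmetry, 2 for a 2x1 rectangle."""
    if abs(polygon_area(pts)) < 1e-14:
        raise DegeneratePolygonError("elongation undefined for zero-area cell")
    vals, _ = principal_axes(pts)
    lam_minor = max(vals[1], 0.0)
    if lam_minor < 1e-16:
        return np.inf
    return float(np.sqrt(vals[0] / lam_minor))


def shortest_axis(pts) -> np.ndarray:
    """Unit direction of the minor principal axis through the centroid.

    This is the direction along which a cell divides ("shortest axis"
    rule): the dividing line runs along the minor axis, cutting the cell
    across its long dimension. Near-degenerate (isotropic) tensors are
    tie-broken toward the +x axis.
    """
    vals, vecs = principal_axes(pts)
    if vals[0] - vals[1] < 1e-12 * max(vals[0], 1e-30):
        return np.array([1.0, 0.0])
    v = vecs[:, 1]
    # canonical sign: prefer +x half-plane, then +y
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v / np.linalg.norm(v)


def _orient(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def segments_intersect(p1, p2, q1, q2, eps: float = 1e-12) -> bool:
    """Proper segment intersection test (shared endpoints do not count)."""
    d1 = _orient(q1, q2, p1)
    d2 = _orient(q1, q2, p2)
    d3 = _orient(p1, p2, q1)
    d4 = _orient(p1, p2, q2)
    return (d1 * d2 < -eps) and (d3 * d4 < -eps)


def segment_intersection_point(p1, p2, q1, q2):
    """Intersection point of segments, or ``None`` when parallel/disjoint."""
    p1, p2, q1, q2 = (np.asarray(v, float) for v in (p1, p2, q1, q2))
    r = p2 - p1
    s = q2 - q1
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < 1e-14:
        return None
    t = ((q1[0] - p1[0]) * s[1] - (q1[1] - p1[1]) * s[0]) / denom
    u = ((q1[0] - p1[0]) * r[1] - (q1[1] - p1[1]) * r[0]) / denom
    if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
        return p1 + t * r
    return None


def point_segment_distance(p, a, b):
    """Distance from point ``p`` to segment ``ab`` and the projection parameter."""
    p, a, b = (np.asarray(v, float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-30:
        return float(np.linalg.norm(p - a)), 0.0
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t


def is_simple_polygon(pts) -> bool:
    """True when no two non-adjacent edges cross (shapely-backed)."""
    import shapely.geometry as sg

    pts = _as_ring(pts)
    return sg.Polygon(pts).is_valid
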