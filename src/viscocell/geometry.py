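"""Planar ring geometry: areas, normals, point-segment distances.

Rings are closed node loops stored as (n, 2) float arrays, ordered
counterclockwise (signed area > 0), indices 0-based.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Degenerate or invalid planar geometry."""


def signed_area(ring: np.ndarray) -> float:
    """Shoelace signed area of a closed ring (positive if counterclockwise)."""
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[0] < 3 or ring.shape[1] != 2:
        raise GeometryError("ring must be an (n>=3, 2) array")
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_area(ring: np.ndarray) -> float:
    """Area (um^2) of a counterclockwise closed simple ring.

    Clockwise input violates the orientation contract and is rejected.
    """
    a = signed_area(ring)
    if a <= 0:
        raise GeometryError("ring is clockwise or degenerate; contract is CCW")
    return a


def centroid(ring: np.ndarray) -> np.ndarray:
    """Vertex centroid (mean of node positions)."""
    return np.asarray(ring, dtype=float).mean(axis=0)


def segment_lengths(ring: np.ndarray) -> np.ndarray:
    """Length of segment i -> i+1 (mod n) for each i."""
    ring = np.asarray(ring, dtype=float)
    return np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)


def perimeter(ring: np.ndarray) -> float:
    return float(segment_lengths(ring).sum())


def outward_normals(ring: np.ndarray) -> np.ndarray:
    """Unit outward normal at every node of a CCW ring.

    The normal at node i is perpendicular to the chord joining its two ring
    neighbours (i-1, i+1) and points away from the interior: for a CCW ring
    the right-hand perpendicular (ty, -tx) of the neighbour chord is outward.
    """
    ring = np.asarray(ring, dtype=float)
    if ring.shape[0] < 3:
        raise GeometryError("need >= 3 nodes for normals")
    chord = np.roll(ring, -1, axis=0) - np.roll(ring, 1, axis=0)
    L = np.linalg.norm(chord, axis=1)
    if np.any(L < 1e-12):
        raise GeometryError("zero-length neighbour chord (coincident neighbours)")
    t = chord / L[:, None]
    return np.stack([t[:, 1], -t[:, 0]], axis=1)


def outward_normal(ring: np.ndarray, index: int) -> np.ndarray:
    """Unit outward normal at one node (see :func:`outward_normals`)."""
    return outward_normals(ring)[index]


def is_simple(ring: np.ndarray) -> bool:
    """True if the closed ring does not self-intersect."""
    return Polygon(np.asarray(ring, dtype=float)).is_valid


def point_segment_distance(p, a, b):
    """Euclidean distance from point ``p`` to closed segment ``a``-``b``.

    Returns ``(distance, closest_point, s)`` where ``s`` in [0, 1] is the
    barycentric coordinate of the closest point along a -> b.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        raise GeometryError("degenerate segment (coincident endpoints)")
    s = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    c = a + s * ab
    return float(np.linalg.norm(p - c)), c, s


def points_segments_distance(points: np.ndarray, sa: np.ndarray, sb: np.ndarray):
    """Vectorised point/segment distances.

    ``points``: (m, 2); ``sa``, ``sb``: (m, 2) matched segment endpoints.
    Returns ``(dist, closest, s)`` arrays of shapes (m,), (m, 2), (m,).
    """
    ab = sb - sa
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom < 1e-24, 1e-24, denom)
    s = np.clip(np.einsum("ij,ij->i", points - sa, ab) / denom, 0.0, 1.0)
    c = sa + s[:, None] * ab
    d = np.linalg.norm(points - c, axis=1)
    return d, c, s


def regular_ring(n: int, radius: float, center=(0.0, 0.0), phase: float = 0.0) -> np.ndarray:
    """CCW regular n-gon of circumscribed ``radius`` (um)."""
    th = phase + 2.0 * np.pi * np.arange(n) / n
    return np.asarray(center, dtype=float) + radius * np.stack([np.cos(th), np.sin(th)], axis=1)


def principal_axes(points: np.ndarray):
    """Eigen-decomposition of the second-moment tensor of a point set.

    Returns ``(evals, evecs)`` sorted ascending; ``evecs[:, i]`` is the unit
    eigenvector for ``evals[i]``.  The minor axis (smaller eigenvalue) is
    perpendicular to the elongation direction.
    """
    pts = np.asarray(points, dtype=float)
    q = pts - pts.mean(axis=0)
    cov = q.T @ q / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    return evals, evecs
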