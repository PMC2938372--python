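"""Tissue-geometry statistics: form factor, edge density, neighbor graphs.

For a patch of n_c cells occupying total area A_T, the cell edge density is
rho = lambda / A_T, where lambda sums the lengths of all internal cell-cell
boundaries plus half the patch perimeter (edges on the free boundary are
shared with a mirror-image patch).  The form factor

    Gamma = rho * sqrt(A_T / n_c)

is dimensionless and minimized, at sqrt(pi), by circular cells; larger values
indicate polygonal or dendritic cultures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon
from shapely.ops import unary_union

from .geometry import polygon_area, segment_lengths, signed_area

SQRT_PI = math.sqrt(math.pi)


@dataclass
class CultureSummary:
    A_T: float                       # um^2, total occupied (patch) area
    n_c: int
    lam: float                       # um, internal boundaries + half perimeter
    rho: float                       # 1/um
    gamma: float
    gamma_interior: float            # form factor of the rim-free subpatch
    mean_neighbors: float
    mean_neighbors_interior: float   # nan when no interior cells
    n_interior: int
    areas: Dict[int, float]
    degrees: Dict[int, int]


class _SubWorld:
    """Restriction of a world to a cell subset (for subpatch statistics)."""

    def __init__(self, world, keep):
        keep = set(keep)
        self.cells = {cid: c for cid, c in world.cells.items() if cid in keep}
        self.adhesion_rule = getattr(world, "adhesion_rule", None)
        self.bonds = {
            key: b
            for key, b in getattr(world, "bonds", {}).items()
            if key[0][0] in keep and key[1][0] in keep
        }


def interior_form_factor(world, eps: Optional[float] = None) -> float:
    """Form factor of the interior (rim-free) cell subpatch.

    Rim cells are partly free-surface and dominate the patch statistics of a
    small colony; the interior subpatch isolates the packing geometry.
    Returns nan when there are no interior cells.
    """
    interior = interior_cells(world, eps)
    if not interior:
        return float("nan")
    return form_factor(_SubWorld(world, interior), eps)


def _live_cells(world):
    return {cid: c for cid, c in world.cells.items() if getattr(c, "state", "") != "apoptotic"}


def _default_eps(world) -> float:
    rule = getattr(world, "adhesion_rule", None)
    return rule.d_a if rule is not None else 1.5


def shared_boundaries(world, eps: Optional[float] = None):
    """Internal boundary length per cell pair, plus per-cell external length.

    A membrane segment is internal when its midpoint lies within ``eps`` of
    another live cell's membrane polyline; each physical interface is counted
    once (both sides detect it, so pair lengths are averaged).  Returns
    ``(pair_lengths, external)`` with ``pair_lengths[(i, j)]`` for i < j.
    """
    eps = eps if eps is not None else _default_eps(world)
    cells = _live_cells(world)
    ids = sorted(cells)
    rings = {cid: LinearRing(cells[cid].mem_pos) for cid in ids}
    one_sided: Dict[Tuple[int, int], float] = {}
    external: Dict[int, float] = {}
    for cid in ids:
        pos = cells[cid].mem_pos
        seg_len = segment_lengths(pos)
        mids = 0.5 * (pos + np.roll(pos, -1, axis=0))
        pts = shapely.points(mids)
        best_d = np.full(len(mids), np.inf)
        best_j = np.full(len(mids), -1, dtype=np.int64)
        for j in ids:
            if j == cid:
                continue
            d = shapely.distance(pts, rings[j])
            closer = d < best_d
            best_d[closer] = d[closer]
            best_j[closer] = j
        internal = best_d < eps
        external[cid] = float(seg_len[~internal].sum())
        for j in np.unique(best_j[internal]):
            L = float(seg_len[internal & (best_j == j)].sum())
            one_sided[(cid, int(j))] = L
    pair_lengths: Dict[Tuple[int, int], float] = {}
    for (i, j), L in one_sided.items():
        key = (i, j) if i < j else (j, i)
        pair_lengths[key] = pair_lengths.get(key, 0.0) + 0.5 * L
    return pair_lengths, external


def patch(world, eps: Optional[float] = None):
    """Occupied patch: morphological closing of the union of cell polygons.

    Adherent membranes sit a junction rest length apart, so the union of the
    raw polygons is closed with a buffer of eps/2 to fuse touching cells
    without inflating the patch.
    """
    eps = eps if eps is not None else _default_eps(world)
    cells = _live_cells(world)
    if not cells:
        raise ValueError("empty world: no live cells")
    polys = [Polygon(c.mem_pos) for c in cells.values()]
    delta = eps / 2.0
    return unary_union([p.buffer(delta) for p in polys]).buffer(-delta)


def edge_density(world, eps: Optional[float] = None):
    """Cell edge density rho = lambda/A_T; returns (rho, lam, A_T)."""
    eps = eps if eps is not None else _default_eps(world)
    pair_lengths, _ = shared_boundaries(world, eps)
    geom = patch(world, eps)
    A_T = geom.area
    if A_T <= 0:
        raise ValueError("degenerate patch area")
    lam = sum(pair_lengths.values()) + 0.5 * geom.length
    return lam / A_T, lam, A_T


def form_factor(world, eps: Optional[float] = None) -> float:
    """Gamma = rho * sqrt(A_T / n_c) (>= sqrt(pi) for circular cells)."""
    n_c = len(_live_cells(world))
    if n_c == 0:
        raise ValueError("form factor undefined for an empty culture")
    rho, _, A_T = edge_density(world, eps)
    return rho * math.sqrt(A_T / n_c)


def interior_cells(world, eps: Optional[float] = None):
    """Cells with no free (outer-boundary) perimeter share.

    A cell is interior when none of its membrane nodes lies within ``eps`` of
    the patch's outer boundary ring(s); pockets fully enclosed by the tissue
    (patch holes) do not make their surrounding cells exterior.
    """
    eps = eps if eps is not None else _default_eps(world)
    cells = _live_cells(world)
    geom = patch(world, eps)
    shells = (
        [geom.exterior]
        if geom.geom_type == "Polygon"
        else [g.exterior for g in geom.geoms]
    )
    out = []
    for cid, c in cells.items():
        pts = shapely.points(c.mem_pos)
        d = np.min([shapely.distance(pts, sh) for sh in shells], axis=0)
        if float(d.min()) > eps:
            out.append(cid)
    return out


def neighbor_graph(world, eps: Optional[float] = None):
    """Cell adjacency graph and neighbor statistics.

    Cells are adjacent when they share internal boundary length (> 0) or hold
    at least one adhesion bond.  Returns ``(graph, mean_degree,
    mean_degree_interior)``; the interior mean averages over cells with no
    free-boundary perimeter (see :func:`interior_cells`) and is nan when
    there are none.
    """
    eps = eps if eps is not None else _default_eps(world)
    cells = _live_cells(world)
    pair_lengths, _ = shared_boundaries(world, eps)
    g = nx.Graph()
    g.add_nodes_from(cells)
    for (i, j), L in pair_lengths.items():
        if L > 0:
            g.add_edge(i, j, length=L)
    for (ra, rb) in getattr(world, "bonds", {}):
        i, j = ra[0], rb[0]
        if i in cells and j in cells and i != j:
            g.add_edge(*sorted((i, j)))
    degrees = dict(g.degree())
    mean_deg = float(np.mean(list(degrees.values()))) if degrees else float("nan")
    interior = interior_cells(world, eps) if cells else []
    mean_int = (
        float(np.mean([degrees[c] for c in interior])) if interior else float("nan")
    )
    return g, mean_deg, mean_int


def culture_summary(world, eps: Optional[float] = None) -> CultureSummary:
    """One-shot tissue summary of the current frame."""
    eps = eps if eps is not None else _default_eps(world)
    cells = _live_cells(world)
    if not cells:
        raise ValueError("empty world: no live cells")
    pair_lengths, external = shared_boundaries(world, eps)
    geom = patch(world, eps)
    A_T = geom.area
    lam = sum(pair_lengths.values()) + 0.5 * geom.length
    rho = lam / A_T
    n_c = len(cells)
    g, mean_deg, mean_int = neighbor_graph(world, eps)
    interior = interior_cells(world, eps)
    return CultureSummary(
        A_T=A_T,
        n_c=n_c,
        lam=lam,
        rho=rho,
        gamma=rho * math.sqrt(A_T / n_c),
        gamma_interior=interior_form_factor(world, eps),
        mean_neighbors=mean_deg,
        mean_neighbors_interior=mean_int,
        n_interior=len(interior),
        areas={cid: abs(signed_area(c.mem_pos)) for cid, c in cells.items()},
        degrees=dict(g.degree()),
    )


def metrics_row(world, eps: Optional[float] = None) -> dict:
    """Flat dict form of :func:`culture_summary` for time-series logging."""
    s = culture_summary(world, eps)
    return {
        "n_c": s.n_c,
        "A_T": s.A_T,
        "lambda": s.lam,
        "rho": s.rho,
        "gamma": s.gamma,
        "gamma_interior": s.gamma_interior,
        "mean_neighbors": s.mean_neighbors,
        "mean_neighbors_interior": s.mean_neighbors_interior,
        "n_interior": s.n_interior,
    }
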