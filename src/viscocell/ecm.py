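"""Extracellular matrix as a series chain of Kelvin-Voigt subunits.

In cross-section the ECM is a polyline (open line) or enclosed curve (ring)
of nodes joined consecutively by ``ecm_chain`` subunits; its nodes interact
with cell membrane points through the same adhesion/repulsion machinery as
cell-cell contacts.  In 2D-culture mode the substrate is instead represented
by a scalar drag field D(x, y): the adhesion intensity of a point to the
substrate is equivalent to its drag coefficient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterator, Optional

import numpy as np

from .config import EcmParams
from .elements import RING_ECM, Node, VoigtElement
from .geometry import regular_ring

_ecm_ids = itertools.count(10_000)  # offset so cell/ecm ids never collide


class ConfigurationError(ValueError):
    pass


class ECMChain:
    """Chain of consecutively connected Voigt subunits (open or closed)."""

    def __init__(
        self,
        pos: np.ndarray,
        params: EcmParams,
        *,
        closed: bool,
        rigid: bool = False,
        drag_profile: Optional[np.ndarray] = None,
        eid: Optional[int] = None,
    ) -> None:
        self.id = next(_ecm_ids) if eid is None else eid
        self.pos = np.asarray(pos, dtype=float)
        self.vel = np.zeros_like(self.pos)
        self.closed = bool(closed)
        self.rigid = bool(rigid)
        self.params = params
        m = len(self.pos)
        ne = m if closed else m - 1
        seg = self.segment_vectors()
        self.k = np.full(ne, params.k)
        self.eta = np.full(ne, params.eta)
        self.L0 = np.linalg.norm(seg, axis=1)  # built at rest
        self.drag = (
            np.full(m, params.drag)
            if drag_profile is None
            else np.asarray(drag_profile, dtype=float)
        )
        if len(self.drag) != m:
            raise ConfigurationError("drag_profile length must match node count")

    @property
    def n(self) -> int:
        return len(self.pos)

    @property
    def n_elements(self) -> int:
        return self.n if self.closed else self.n - 1

    def segment_vectors(self) -> np.ndarray:
        if self.closed:
            return np.roll(self.pos, -1, axis=0) - self.pos
        return self.pos[1:] - self.pos[:-1]

    def element_endpoints(self):
        """(index a, index b) arrays of the chain elements."""
        m = self.n
        ia = np.arange(self.n_elements)
        ib = (ia + 1) % m if self.closed else ia + 1
        return ia, ib

    def chain_forces(self, viscous: bool = False) -> np.ndarray:
        """Per-node force from the chain's own subunits (zero when rigid-frozen
        geometry is at rest; still computed for bookkeeping)."""
        from .elements import pair_forces

        ia, ib = self.element_endpoints()
        if viscous:
            fa = pair_forces(self.pos[ia], self.pos[ib], self.vel[ia], self.vel[ib],
                             self.k, self.eta, self.L0)
        else:
            fa = pair_forces(self.pos[ia], self.pos[ib], None, None, self.k, None, self.L0)
        f = np.zeros_like(self.pos)
        np.add.at(f, ia, fa)
        np.add.at(f, ib, -fa)
        return f

    def split_element(self, e: int, relax: bool = True) -> None:
        """Insert a node at the midpoint of chain element ``e`` (matrix
        remodeling: the chain can freely gain points as it is stretched).
        With ``relax=True`` the two new subunits rest at half the current
        element length; otherwise they share the old rest length."""
        ia, ib = self.element_endpoints()
        a, b = int(ia[e]), int(ib[e])
        mid = 0.5 * (self.pos[a] + self.pos[b])
        half = (
            0.5 * float(np.linalg.norm(self.pos[b] - self.pos[a]))
            if relax
            else 0.5 * self.L0[e]
        )
        self.pos = np.insert(self.pos, e + 1, mid, axis=0)
        self.vel = np.insert(self.vel, e + 1, 0.5 * (self.vel[a] + self.vel[b]), axis=0)
        self.drag = np.insert(self.drag, e + 1, 0.5 * (self.drag[a] + self.drag[b]))
        self.k = np.insert(self.k, e + 1, self.k[e])
        self.eta = np.insert(self.eta, e + 1, self.eta[e])
        self.L0 = np.insert(self.L0, e + 1, half)
        self.L0[e] = half

    def eta_sums(self) -> np.ndarray:
        ia, ib = self.element_endpoints()
        s = np.zeros(self.n)
        np.add.at(s, ia, self.eta)
        np.add.at(s, ib, self.eta)
        return s

    def iter_nodes(self) -> Iterator[Node]:
        for i in range(self.n):
            yield Node(
                id=(self.id, RING_ECM, i),
                owner=self.id,
                ring="ecm",
                index=i,
                position=self.pos[i].copy(),
                velocity=self.vel[i].copy(),
                mass=0.0,
                drag=float(self.drag[i]),
                label="none",
                fixed=self.rigid,
            )

    def iter_elements(self) -> Iterator[VoigtElement]:
        ia, ib = self.element_endpoints()
        for e in range(self.n_elements):
            yield VoigtElement(
                (self.id, RING_ECM, int(ia[e])), (self.id, RING_ECM, int(ib[e])),
                self.k[e], self.eta[e], self.L0[e], "ecm_chain",
            )


def build_ecm(
    geometry: str,
    params: Optional[EcmParams] = None,
    *,
    length: float = 100.0,
    radius: float = 20.0,
    gap_width: float = 0.0,
    gap_depth: float = 0.0,
    spacing: Optional[float] = None,
    center=(0.0, 0.0),
    rigid: bool = False,
    drag_dip_depth: float = 0.0,
    drag_dip_sigma: float = 10.0,
) -> ECMChain:
    """Construct a named ECM geometry at rest.

    geometry:
        ``line``           horizontal segment of ``length`` centred at ``center``
        ``ring``           closed circle of ``radius``
        ``line_with_gap``  line with a rectangular notch of width ``gap_width``
                           and depth ``gap_depth`` cut downward at the centre
        ``ring_with_hole`` open circular arc (a ring with a missing sector of
                           arc length ``gap_width``)

    ``drag_dip_depth`` in (0, 1] carves a Gaussian dip in the per-node drag
    profile at the chain centre (the locally "thinned" matrix of the
    tensegrity scenario).
    """
    params = params or EcmParams()
    h = spacing if spacing is not None else params.spacing
    cx, cy = center
    if geometry == "line":
        m = int(round(length / h)) + 1
        x = cx + np.linspace(-length / 2, length / 2, m)
        pos = np.stack([x, np.full(m, cy)], axis=1)
        closed = False
    elif geometry == "ring":
        m = max(8, int(round(2 * np.pi * radius / h)))
        pos = regular_ring(m, radius, center)
        closed = True
    elif geometry == "line_with_gap":
        if gap_width <= 0:
            raise ConfigurationError("gap_width must be positive for line_with_gap")
        depth = gap_depth if gap_depth > 0 else 2 * gap_width
        half = gap_width / 2
        xs_left = np.arange(cx - length / 2, cx - half + 1e-9, h)
        xs_right = np.arange(cx + half, cx + length / 2 + 1e-9, h)
        down = np.arange(cy, cy - depth - 1e-9, -h)
        up = down[::-1]
        parts = [
            np.stack([xs_left, np.full(len(xs_left), cy)], axis=1),
            np.stack([np.full(len(down) - 1, cx - half), down[1:]], axis=1),
            np.stack(
                [np.arange(cx - half + h, cx + half - h + 1e-9, h),
                 np.full(max(0, len(np.arange(cx - half + h, cx + half - h + 1e-9, h))), cy - depth)],
                axis=1,
            ),
            np.stack([np.full(len(up) - 1, cx + half), up[:-1]], axis=1),
            np.stack([xs_right, np.full(len(xs_right), cy)], axis=1),
        ]
        pos = np.concatenate([p for p in parts if len(p)], axis=0)
        closed = False
    elif geometry == "ring_with_hole":
        m = max(8, int(round(2 * np.pi * radius / h)))
        hole_arc = gap_width / radius if gap_width > 0 else np.pi / 4
        th = np.linspace(hole_arc / 2, 2 * np.pi - hole_arc / 2, m)
        pos = np.stack([cx + radius * np.cos(th), cy + radius * np.sin(th)], axis=1)
        closed = False
    else:
        raise ConfigurationError(f"unknown ECM geometry {geometry!r}")

    drag_profile = np.full(len(pos), params.drag)
    if drag_dip_depth > 0.0:
        d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
        drag_profile *= 1.0 - drag_dip_depth * np.exp(-d2 / (2 * drag_dip_sigma**2))
    return ECMChain(pos, params, closed=closed, rigid=rigid, drag_profile=drag_profile)


class SubstrateField:
    """Scalar drag field D(x, y) for 2D-culture mode."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], label: str = "custom"):
        self._fn = fn
        self.label = label

    @classmethod
    def uniform(cls, value: float) -> "SubstrateField":
        return cls(lambda p: np.full(len(np.atleast_2d(p)), float(value)),
                   label=f"uniform({value})")

    @classmethod
    def linear_gradient(cls, d_min: float, d_max: float, axis: int = 0,
                        x0: float = -50.0, x1: float = 50.0) -> "SubstrateField":
        def fn(p):
            p = np.atleast_2d(p)
            t = np.clip((p[:, axis] - x0) / (x1 - x0), 0.0, 1.0)
            return d_min + t * (d_max - d_min)

        return cls(fn, label=f"gradient({d_min}->{d_max})")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(np.atleast_2d(points)), dtype=float)


def substrate_drag(world, node_position) -> float:
    """Drag coefficient at a node position in 2D-culture mode.

    Raises :class:`ConfigurationError` if the world has no substrate field.
    """
    if getattr(world, "substrate", None) is None:
        raise ConfigurationError("world is not in 2D-culture mode (no substrate field)")
    return float(world.substrate(np.asarray(node_position))[0])
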