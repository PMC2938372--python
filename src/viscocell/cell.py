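"""The deformable cell: two closed Kelvin-Voigt node rings plus internal wiring.

A cell is a closed membrane ring and a closed nucleus ring of equal node
count n (counterclockwise, 0-based), coupled by four element categories:

* ``membrane``          ring subunit i joins membrane nodes i and i+1 (mod n)
* ``nuclear_membrane``  same topology on the nucleus ring
* ``radial``            cytoskeleton subunit i joins membrane node i to
                        nucleus node i
* ``nuclear_chord``     nucleoskeleton subunit i joins nucleus node i to
                        node (i + floor(n/2)) mod n (diametral), so every
                        nucleus node carries exactly two chord endpoints

Element parameters are stored as per-category arrays so force evaluation is
vectorised over the ring.  The cytoplasm acts as a pressure differential
P_in - P_env applied along the outward membrane normal, with each node
supporting half the length of its two adjacent segments (lumped-load
quadrature: the net pressure force on a closed ring is exactly zero).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from shapely.geometry import Polygon

from .config import CellParams
from .elements import (
    LABELS,
    RING_MEMBRANE,
    RING_NUCLEUS,
    Node,
    VoigtElement,
    pair_forces,
)
from .geometry import (
    GeometryError,
    outward_normals,
    polygon_area,
    regular_ring,
    segment_lengths,
    signed_area,
)

_cell_ids = itertools.count(0)


class StructuralError(ValueError):
    """Ring/element wiring violates the cell's structural contract."""


@dataclass
class ElementArrays:
    """Per-category vectorised subunit parameters."""

    k: np.ndarray
    eta: np.ndarray
    L0: np.ndarray

    @classmethod
    def uniform(cls, n: int, k: float, eta: float, L0) -> "ElementArrays":
        L0 = np.broadcast_to(np.asarray(L0, dtype=float), (n,)).copy()
        return cls(np.full(n, float(k)), np.full(n, float(eta)), L0)

    def copy(self) -> "ElementArrays":
        return ElementArrays(self.k.copy(), self.eta.copy(), self.L0.copy())


def chord_rest_length(n: int, nucleus_rest_radius: float) -> float:
    """Rest length of a diametral chord on a regular n-gon nucleus."""
    return 2.0 * nucleus_rest_radius * np.sin(np.pi * (n // 2) / n)


class Cell:
    """One deformable cell agent."""

    def __init__(
        self,
        cid: int,
        mem_pos: np.ndarray,
        nuc_pos: np.ndarray,
        params: CellParams,
        *,
        mem_el: ElementArrays,
        nucmem_el: ElementArrays,
        radial: ElementArrays,
        chord: Optional[ElementArrays],
        V_rest: float,
        nucleus_rest_radius: float,
    ) -> None:
        n = len(mem_pos)
        if len(nuc_pos) != n:
            raise StructuralError("membrane and nucleus rings must have equal node count")
        self.id = cid
        self.params = params
        self.mem_pos = np.asarray(mem_pos, dtype=float)
        self.nuc_pos = np.asarray(nuc_pos, dtype=float)
        self.mem_vel = np.zeros((n, 2))
        self.nuc_vel = np.zeros((n, 2))
        self.mem_drag = np.full(n, params.drag_membrane)
        self.nuc_drag = np.full(n, params.drag_nucleus)
        self.mem_mass = np.full(n, params.mass_cytoskeleton / n)
        self.nuc_mass = np.full(n, params.mass_nucleus / n)
        self.labels = np.zeros(n, dtype=np.int8)  # codes into elements.LABELS
        self.mem_el = mem_el
        self.nucmem_el = nucmem_el
        self.radial = radial
        self.chord = chord            # None while mitotic (nucleoskeleton collapsed)
        self.V_rest = float(V_rest)
        self.V_init_rest = float(V_rest)
        self.nucleus_rest_radius = float(nucleus_rest_radius)
        self.P_in = params.p_in
        self.c_s = params.c_s
        self.c_g = params.c_g
        self.state = "quiescent"      # quiescent | growing | mitotic | apoptotic
        self.growth_region = "growth"  # hysteresis memory of Eq-style volume gating
        self.polarized = False
        self.motile = False
        self.motility = None          # MotilityBlock, set by processes.enable_motility
        self.mitosis = None           # MitosisState while state == "mitotic"
        self.n0 = n                   # founder ring size (division repopulation target)
        self.next_growth_time = 0.0
        self.division_enabled = True
        self.growth_enabled = True
        self.ecm_contact_lost_since: Optional[float] = None
        self._eta_cache = None        # (mem_eta_sum, nuc_eta_sum)

    # ------------------------------------------------------------------ build
    @classmethod
    def build(
        cls,
        params: CellParams,
        center=(0.0, 0.0),
        phase: float = 0.0,
        cid: Optional[int] = None,
    ) -> "Cell":
        """Concentric regular-ring cell with all elements at rest length."""
        n, R, rn = params.n_points, params.radius, params.nucleus_radius
        if rn >= R:
            raise ValueError("nucleus radius must be smaller than cell radius")
        mem = regular_ring(n, R, center, phase)
        nuc = regular_ring(n, rn, center, phase)
        mem_el = ElementArrays.uniform(
            n, params.k_membrane, params.eta_membrane, 2 * R * np.sin(np.pi / n)
        )
        nucmem_el = ElementArrays.uniform(
            n, params.k_nuc_membrane, params.eta_nuc_membrane, 2 * rn * np.sin(np.pi / n)
        )
        radial = ElementArrays.uniform(n, params.k_radial, params.eta_radial, R - rn)
        chord = ElementArrays.uniform(
            n, params.k_chord, params.eta_chord, chord_rest_length(n, rn)
        )
        V_rest = 0.5 * n * R * R * np.sin(2 * np.pi / n)
        cell = cls(
            next(_cell_ids) if cid is None else cid,
            mem,
            nuc,
            params,
            mem_el=mem_el,
            nucmem_el=nucmem_el,
            radial=radial,
            chord=chord,
            V_rest=V_rest,
            nucleus_rest_radius=rn,
        )
        cell.validate()
        return cell

    # ------------------------------------------------------------- structure
    @property
    def n(self) -> int:
        return len(self.mem_pos)

    def chord_partner(self, i: int) -> int:
        return (i + self.n // 2) % self.n

    def area(self) -> float:
        """Current volume proxy V_cur (2D area of the membrane ring), um^2."""
        return polygon_area(self.mem_pos)

    def nucleus_centroid(self) -> np.ndarray:
        return self.nuc_pos.mean(axis=0)

    def centroid(self) -> np.ndarray:
        return self.mem_pos.mean(axis=0)

    def membrane_polygon(self) -> Polygon:
        return Polygon(self.mem_pos)

    def validate(self, check_nucleus_inside: bool = True) -> None:
        if self.n < 3:
            raise StructuralError("rings need >= 3 nodes")
        if len(self.nuc_pos) != self.n:
            raise StructuralError("membrane and nucleus rings must have equal node count")
        for name, arrs in (
            ("membrane", self.mem_el),
            ("nuclear_membrane", self.nucmem_el),
            ("radial", self.radial),
        ):
            if len(arrs.k) != self.n:
                raise StructuralError(f"{name} element count != ring size")
        if self.chord is not None and len(self.chord.k) != self.n:
            raise StructuralError("chord element count != ring size")
        if signed_area(self.mem_pos) <= 0 or signed_area(self.nuc_pos) <= 0:
            raise StructuralError("rings must be counterclockwise (signed area > 0)")
        mem_poly = Polygon(self.mem_pos)
        nuc_poly = Polygon(self.nuc_pos)
        if not (mem_poly.is_valid and nuc_poly.is_valid):
            raise StructuralError("ring self-intersects")
        if check_nucleus_inside and not mem_poly.contains(nuc_poly):
            raise StructuralError("nucleus ring must lie inside the membrane ring")
        if self.V_rest <= 0:
            raise StructuralError("V_rest must be positive")

    # ---------------------------------------------------------------- lumping
    def eta_sums(self):
        """Per-node sum of incident dashpot viscosities (for drag lumping)."""
        if self._eta_cache is None:
            n = self.n
            mem = self.mem_el.eta + np.roll(self.mem_el.eta, 1) + self.radial.eta
            nuc = (
                self.nucmem_el.eta
                + np.roll(self.nucmem_el.eta, 1)
                + self.radial.eta
            )
            if self.chord is not None:
                h = n // 2
                nuc = nuc + self.chord.eta + np.roll(self.chord.eta, h)
            self._eta_cache = (mem, nuc)
        return self._eta_cache

    def invalidate_caches(self) -> None:
        self._eta_cache = None

    # ------------------------------------------------------------- insertion
    def insert_node(self, k: int, grow: bool = False) -> None:
        """Insert a node between ring positions k and k+1 on both rings.

        Adds one membrane, one nuclear-membrane and one radial subunit with
        parameters averaged from their first homogeneous neighbours, and
        re-pairs the nuclear chords for the new ring size.  With ``grow=True``
        the rest geometry is rescaled for a growth event: total perimeter rest
        lengths and radial rest lengths x (n+1)/n, V_rest x ((n+1)/n)^2.
        With ``grow=False`` (division repopulation) rest totals are preserved.
        """
        n = self.n
        k = k % n
        k1 = (k + 1) % n
        scale = (n + 1) / n

        for ring_name in ("mem", "nuc"):
            pos = getattr(self, f"{ring_name}_pos")
            vel = getattr(self, f"{ring_name}_vel")
            mid = 0.5 * (pos[k] + pos[k1])
            vmid = 0.5 * (vel[k] + vel[k1])
            setattr(self, f"{ring_name}_pos", np.insert(pos, k + 1, mid, axis=0))
            setattr(self, f"{ring_name}_vel", np.insert(vel, k + 1, vmid, axis=0))

        for arr_name in ("mem_drag", "nuc_drag", "mem_mass", "nuc_mass"):
            arr = getattr(self, arr_name)
            setattr(
                self, arr_name, np.insert(arr, k + 1, 0.5 * (arr[k] + arr[k1]))
            )
        self.labels = np.insert(self.labels, k + 1, self.labels[k])

        for el_name in ("mem_el", "nucmem_el"):
            el = getattr(self, el_name)
            km = (k - 1) % n
            kp = k1  # old element after the split one
            knew = 0.5 * (el.k[km] + el.k[k]), 0.5 * (el.k[k] + el.k[kp])
            enew = 0.5 * (el.eta[km] + el.eta[k]), 0.5 * (el.eta[k] + el.eta[kp])
            half = 0.5 * el.L0[k]
            el.k = np.concatenate([el.k[: k + 1], [knew[1]], el.k[k + 1 :]])
            el.k[k] = knew[0]
            el.eta = np.concatenate([el.eta[: k + 1], [enew[1]], el.eta[k + 1 :]])
            el.eta[k] = enew[0]
            el.L0 = np.concatenate([el.L0[: k + 1], [half], el.L0[k + 1 :]])
            el.L0[k] = half
            if grow:
                # total rest perimeter x (n+1)/n, redistributed uniformly so
                # ring spacing stays even as the cell grows (a count-based
                # division split then halves the geometry too)
                el.L0[:] = el.L0.sum() * scale / len(el.L0)

        r = self.radial
        r.k = np.insert(r.k, k + 1, 0.5 * (r.k[k] + r.k[k1]))
        r.eta = np.insert(r.eta, k + 1, 0.5 * (r.eta[k] + r.eta[k1]))
        r.L0 = np.insert(r.L0, k + 1, 0.5 * (r.L0[k] + r.L0[k1]))
        if grow:
            r.L0 *= scale
            self.nucleus_rest_radius *= scale
            self.V_rest *= scale * scale

        if self.chord is not None:
            m = self.n  # updated ring size (positions already extended)
            kc = float(self.chord.k.mean())
            ec = float(self.chord.eta.mean())
            self.chord = ElementArrays.uniform(
                m, kc, ec, chord_rest_length(m, self.nucleus_rest_radius)
            )
        self.invalidate_caches()

    # -------------------------------------------------------------- node API
    def iter_nodes(self) -> Iterator[Node]:
        """Snapshot Node records (copies) for I/O and inspection."""
        for ring_code, pos, vel, drag, mass in (
            (RING_MEMBRANE, self.mem_pos, self.mem_vel, self.mem_drag, self.mem_mass),
            (RING_NUCLEUS, self.nuc_pos, self.nuc_vel, self.nuc_drag, self.nuc_mass),
        ):
            for i in range(self.n):
                yield Node(
                    id=(self.id, ring_code, i),
                    owner=self.id,
                    ring="membrane" if ring_code == RING_MEMBRANE else "nucleus",
                    index=i,
                    position=pos[i].copy(),
                    velocity=vel[i].copy(),
                    mass=float(mass[i]),
                    drag=float(drag[i]),
                    label=LABELS[self.labels[i]] if ring_code == RING_MEMBRANE else "none",
                    fixed=False,
                )

    def iter_elements(self) -> Iterator[VoigtElement]:
        n = self.n
        for i in range(n):
            j = (i + 1) % n
            yield VoigtElement(
                (self.id, RING_MEMBRANE, i), (self.id, RING_MEMBRANE, j),
                self.mem_el.k[i], self.mem_el.eta[i], self.mem_el.L0[i], "membrane",
            )
            yield VoigtElement(
                (self.id, RING_NUCLEUS, i), (self.id, RING_NUCLEUS, j),
                self.nucmem_el.k[i], self.nucmem_el.eta[i], self.nucmem_el.L0[i],
                "nuclear_membrane",
            )
            yield VoigtElement(
                (self.id, RING_MEMBRANE, i), (self.id, RING_NUCLEUS, i),
                self.radial.k[i], self.radial.eta[i], self.radial.L0[i], "radial",
            )
            if self.chord is not None:
                yield VoigtElement(
                    (self.id, RING_NUCLEUS, i),
                    (self.id, RING_NUCLEUS, self.chord_partner(i)),
                    self.chord.k[i], self.chord.eta[i], self.chord.L0[i],
                    "nuclear_chord",
                )


# ----------------------------------------------------------------- force ops
def _ring_el_forces(pos, vel, el: ElementArrays, viscous: bool):
    """Per-node force from the closed-ring subunits (element i joins i, i+1)."""
    nxt_pos = np.roll(pos, -1, axis=0)
    if viscous:
        fa = pair_forces(pos, nxt_pos, vel, np.roll(vel, -1, axis=0), el.k, el.eta, el.L0)
    else:
        fa = pair_forces(pos, nxt_pos, None, None, el.k, None, el.L0)
    # node j is endpoint a of element j and endpoint b of element j-1
    return fa - np.roll(fa, 1, axis=0)


def _radial_el_forces(cell: Cell, viscous: bool):
    """Force of radial subunit i on its membrane endpoint (negate for nucleus)."""
    if viscous:
        return pair_forces(
            cell.mem_pos, cell.nuc_pos, cell.mem_vel, cell.nuc_vel,
            cell.radial.k, cell.radial.eta, cell.radial.L0,
        )
    return pair_forces(
        cell.mem_pos, cell.nuc_pos, None, None, cell.radial.k, None, cell.radial.L0
    )


def cytoskeleton_forces(cell: Cell, viscous: bool = True) -> np.ndarray:
    """Radial (cytoskeleton) subunit force on each membrane node, (n, 2) nN."""
    return _radial_el_forces(cell, viscous)


def nucleus_forces(cell: Cell, viscous: bool = True) -> np.ndarray:
    """Total structural force on each nucleus node.

    Each nucleus node receives its radial subunit's reaction, its two
    nuclear-membrane ring subunits, and (outside mitosis) its two diametral
    chord subunits.
    """
    f = -_radial_el_forces(cell, viscous)
    f = f + _ring_el_forces(cell.nuc_pos, cell.nuc_vel, cell.nucmem_el, viscous)
    if cell.chord is not None:
        h = cell.n // 2
        partner = (np.arange(cell.n) + h) % cell.n
        pa = cell.nuc_pos
        pb = cell.nuc_pos[partner]
        if viscous:
            fa = pair_forces(pa, pb, cell.nuc_vel, cell.nuc_vel[partner],
                             cell.chord.k, cell.chord.eta, cell.chord.L0)
        else:
            fa = pair_forces(pa, pb, None, None, cell.chord.k, None, cell.chord.L0)
        f = f + fa
        np.add.at(f, partner, -fa)
    return f


def membrane_forces(cell: Cell, viscous: bool = True) -> np.ndarray:
    """Cortical ring subunit force on each membrane node, (n, 2) nN."""
    return _ring_el_forces(cell.mem_pos, cell.mem_vel, cell.mem_el, viscous)


def pressure_forces(cell: Cell, p_env: float = 0.0) -> np.ndarray:
    """Cytoplasmic pressure force (P_in - P_env) on each membrane node.

    Each node supports half its neighbour chord (the segment joining its two
    ring neighbours) along its outward normal: F_i = dP/2 * rot(r_{i+1} -
    r_{i-1}).  The chord vectors telescope around the closed ring, so the
    lumped load integrates to exactly zero net force; on a regular ring the
    supported length equals the adjacent-segment average to O(1/n^2).
    """
    dp = cell.P_in - p_env
    if dp == 0.0:
        return np.zeros_like(cell.mem_pos)
    chord = np.roll(cell.mem_pos, -1, axis=0) - np.roll(cell.mem_pos, 1, axis=0)
    return 0.5 * dp * np.stack([chord[:, 1], -chord[:, 0]], axis=1)


def total_inner_force(cell: Cell, p_env: float = 0.0, viscous: bool = True):
    """Intra-cellular force decomposition.

    Returns ``(f_membrane_nodes, f_nucleus_nodes)``: membrane nodes receive
    cytoskeleton + cortical ring + pressure; nucleus nodes receive radial
    reaction + chords + nuclear-membrane ring.  With no pressure differential
    the grand total over all nodes of an isolated cell vanishes (pairwise
    cancellation), and a closed ring's pressure load integrates to ~0.
    """
    f_mem = (
        cytoskeleton_forces(cell, viscous)
        + membrane_forces(cell, viscous)
        + pressure_forces(cell, p_env)
    )
    return f_mem, nucleus_forces(cell, viscous)
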