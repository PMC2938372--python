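"""Agent rules: growth gating, division surgery, apoptosis, polarity, crawling.

Growth inserts nodes (one membrane + one nucleus node and four subunits per
event) gated by the stop/growth volume regions around the rest volume;
division doubles the rest volume through growth, pulls the nuclear halves
apart while a contractile ring pinches the furrow, and performs ring surgery
into two daughters; apoptosis collapses the rest geometry and removes the
pressure differential until the cell shrinks below a reaping threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .cell import Cell, ElementArrays, StructuralError, chord_rest_length
from .elements import LABEL_CODES, RING_ECM
from .geometry import principal_axes, segment_lengths, signed_area
from .world import World

_daughter_ids = itertools.count(1_000)


# ------------------------------------------------------------------- growth
def growth_state(cell: Cell) -> str:
    """Volume-region gate: 'stop' below c_s*V_rest, 'growth' above c_g*V_rest,
    'intermediate' in between (previous region retained — hysteresis)."""
    try:
        v = cell.area()
    except Exception:
        # transiently degenerate ring under extreme crowding: treat as fully
        # compressed (growth certainly cannot proceed)
        cell.growth_region = "stop"
        return "stop"
    if v <= cell.c_s * cell.V_rest:
        cell.growth_region = "stop"
        return "stop"
    if v >= cell.c_g * cell.V_rest:
        cell.growth_region = "growth"
        return "growth"
    return "intermediate"


def effective_growth_region(cell: Cell) -> str:
    """Current region with hysteresis resolved (intermediate -> memory)."""
    state = growth_state(cell)
    return cell.growth_region if state == "intermediate" else state


def division_target_points(n0: int) -> int:
    """Ring size at which the rest volume has doubled: smallest m with
    (m/n0)^2 >= 2, rounded up to even parity so cytokinesis splits the ring
    into two equal groups (an odd ring forces a one-node imbalance that
    biases the daughter areas)."""
    m = int(math.ceil(n0 * math.sqrt(2.0) - 1e-9))
    return m + (m % 2)


def add_growth_point(cell: Cell, rng: np.random.Generator, world: Optional[World] = None) -> int:
    """One growth event: insert a node at a uniform random ring position.

    Adds four subunits (membrane, nuclear membrane, radial, chord re-pairing)
    with first-neighbour-averaged parameters and rescales the rest geometry
    (perimeters and radial rest lengths x (n+1)/n, V_rest x ((n+1)/n)^2).
    """
    if cell.state in ("mitotic", "apoptotic"):
        raise StructuralError(f"cell {cell.id} cannot grow in state {cell.state}")
    k = int(rng.integers(cell.n))
    cell.insert_node(k, grow=True)
    if world is not None:
        world.remap_bonds_after_insert(cell.id, k)
    cell.state = "growing"
    return k


# ------------------------------------------------------------------ mitosis
@dataclass
class DivisionAxis:
    point: np.ndarray      # anchor: nucleus centre of mass
    direction: np.ndarray  # unit vector along the division axis


@dataclass
class MitosisState:
    axis: DivisionAxis
    group_a: np.ndarray            # bool mask over ring indices (True = group A)
    anchor_index: int              # nearest membrane node to the axis
    u: np.ndarray                  # unit pull direction (orthogonal to axis, toward A)
    F_div_n: float
    F_div_m: float
    L_div: float
    pinch_stop: float = 1.5        # um: furrow-side gap where pinching stops
    order_a: np.ndarray = field(default=None)  # A indices in ring order
    order_b: np.ndarray = field(default=None)


def select_division_axis(cell: Cell) -> DivisionAxis:
    """Division axis through the nucleus centre of mass.

    Unpolarized: the minor principal axis of the membrane-node second-moment
    tensor (perpendicular to the elongation direction).  Polarized: orthogonal
    to the basal (ECM-contacting) membrane stretch.  Degenerate (isotropic)
    tensors tie-break with the axis through membrane node 0.
    """
    anchor = cell.nucleus_centroid()
    basal = cell.labels == LABEL_CODES["basal"]
    if cell.polarized and basal.sum() >= 2:
        pts = cell.mem_pos[basal]
        _, evecs = principal_axes(pts)
        tangent = evecs[:, 1]      # basal stretch direction
        direction = np.array([-tangent[1], tangent[0]])
        return DivisionAxis(anchor, direction / np.linalg.norm(direction))
    evals, evecs = principal_axes(cell.mem_pos)
    if evals[1] - evals[0] <= 1e-6 * max(evals[1], 1e-300):
        d = cell.mem_pos[0] - anchor
        return DivisionAxis(anchor, d / np.linalg.norm(d))
    return DivisionAxis(anchor, evecs[:, 0])  # minor axis


def partition_cell(cell: Cell, axis: DivisionAxis) -> MitosisState:
    """Split the ring into two contiguous groups at the two membrane nodes
    nearest the division axis (one per axis crossing), collapse the
    nucleoskeleton (chords deleted), and mark the cell mitotic.

    Anchoring both boundaries at the actual axis crossings splits the cell
    into two approximately equal parts even when ring spacing is uneven; the
    group sizes stay within a few nodes of n/2.
    """
    n = cell.n
    d = axis.direction
    rel = cell.mem_pos - axis.point
    dist_to_axis = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
    k = int(np.argmin(dist_to_axis))
    # second boundary: nearest node to the axis on the opposite ring half
    offsets = (np.arange(n) - k) % n
    opposite = (offsets >= n // 3) & (offsets <= (2 * n) // 3)
    k2 = int(np.arange(n)[opposite][np.argmin(dist_to_axis[opposite])])
    size_a = (k2 - k) % n
    order_a = (k + np.arange(size_a)) % n
    group_a = np.zeros(n, dtype=bool)
    group_a[order_a] = True
    order_b = (k2 + np.arange(n - size_a)) % n

    u = np.array([-d[1], d[0]])
    ca = cell.nuc_pos[group_a].mean(axis=0)
    cb = cell.nuc_pos[~group_a].mean(axis=0)
    if (ca - cb) @ u < 0:
        u = -u

    cell.chord = None              # nuclear subunits eliminated during mitosis
    cell.invalidate_caches()
    cell.state = "mitotic"
    cell.mitosis = MitosisState(
        axis=axis,
        group_a=group_a,
        anchor_index=k,
        u=u,
        F_div_n=cell.params.F_div_n,
        F_div_m=cell.params.F_div_m,
        L_div=cell.params.L_div,
        order_a=order_a,
        order_b=order_b,
    )
    return cell.mitosis


def nuclear_separation(cell: Cell, state: Optional[MitosisState] = None) -> float:
    state = state or cell.mitosis
    a = cell.nuc_pos[state.group_a].mean(axis=0)
    b = cell.nuc_pos[~state.group_a].mean(axis=0)
    return float(np.linalg.norm(a - b))


def mitosis_forces(cell: Cell, state: Optional[MitosisState] = None):
    """Anaphase pulling + contractile-ring forces; world total exactly zero.

    Nucleus nodes of group A are pulled along +u, group B along -u (group-B
    magnitudes scaled by |A|/|B| so the sums cancel).  The contractile ring
    acts on the membrane boundary nodes of the two A/B interfaces — the
    opposite sides of the cell boundary where the division axis crosses it —
    pulling them toward each other along the axis, which indents the furrow.
    The anaphase pull ramps to zero near the separation threshold so the
    release is not impulsive; the ring keeps acting until the furrow closes.
    """
    state = state or cell.mitosis
    if state is None:
        raise StructuralError("cell is not mitotic")
    n = cell.n
    f_mem = np.zeros((n, 2))
    f_nuc = np.zeros((n, 2))
    sep = nuclear_separation(cell, state)
    ramp = float(np.clip((1.1 * state.L_div - sep) / (0.2 * state.L_div), 0.0, 1.0))
    na = int(state.group_a.sum())
    nb = n - na
    f_nuc[state.group_a] = ramp * state.F_div_n * state.u
    f_nuc[~state.group_a] = -ramp * state.F_div_n * (na / nb) * state.u

    side1, side2 = _interface_pairs(state, n)
    c1 = cell.mem_pos[list(side1)].mean(axis=0)
    c2 = cell.mem_pos[list(side2)].mean(axis=0)
    # the furrow contracts toward the division-plane centre (midpoint of the
    # separating nuclei): the ring is anchored through the spindle, whose
    # reaction acts on the nucleus nodes, so the total stays exactly zero
    target = 0.5 * (
        cell.nuc_pos[state.group_a].mean(axis=0)
        + cell.nuc_pos[~state.group_a].mean(axis=0)
    )
    gap = float(np.linalg.norm(c2 - c1))
    # fades out as the two furrow sides meet so the boundary nodes never
    # cross (the ring must stay simple through cytokinesis)
    pinch = float(np.clip((gap - state.pinch_stop) / state.pinch_stop, 0.0, 1.0))
    if pinch > 0.0:
        reaction = np.zeros(2)
        for side, c in ((side1, c1), (side2, c2)):
            d = target - c
            L = float(np.linalg.norm(d))
            if L > 1e-9:
                pull = 0.5 * pinch * state.F_div_m * d / L
                for p in side:
                    f_mem[p] += pull
                    reaction -= pull
        f_nuc += reaction / n
    return f_mem, f_nuc


def furrow_closed(cell: Cell, state: Optional[MitosisState] = None, slack: float = 2.0) -> bool:
    """True when the two furrow sides have met to within
    ``slack * pinch_stop``; abscission before closure would shear off the
    neck region and violate area bookkeeping."""
    state = state or cell.mitosis
    side1, side2 = _interface_pairs(state, cell.n)
    c1 = cell.mem_pos[list(side1)].mean(axis=0)
    c2 = cell.mem_pos[list(side2)].mean(axis=0)
    return float(np.linalg.norm(c2 - c1)) <= slack * state.pinch_stop


def _interface_pairs(state: MitosisState, n: int):
    k = state.anchor_index
    size_a = int(state.group_a.sum())
    return (
        (k, (k - 1) % n),
        ((k + size_a - 1) % n, (k + size_a) % n),
    )


def split_cell(world: Optional[World], cell: Cell, state: Optional[MitosisState] = None) -> Tuple[Cell, Cell]:
    """Ring surgery into two daughters once the nuclei have separated.

    Boundary-crossing subunits are deleted and each group is re-closed with a
    new first-neighbour subunit; each daughter is repopulated to the founder
    ring size by midpoint insertion between its farthest consecutive nodes,
    its rest volume reset to the founder rest volume, and its nuclear chords
    rebuilt.  The parent's adhesion bonds are dropped (daughters re-adhere on
    the next junction sweep).
    """
    state = state or cell.mitosis
    if state is None:
        raise StructuralError("cell is not mitotic")
    daughters = []
    for order in (state.order_a, state.order_b):
        if len(order) < 3:
            raise StructuralError("division group has fewer than 3 nodes")
        cid = world.new_cell_id() if world is not None else next(_daughter_ids)
        daughters.append(_extract_daughter(cell, order, cid))
    for d in daughters:
        _repopulate(d, cell.n0)
        _renormalize_rest(d)
        # a newborn waits a full attempt period before its first growth
        d.next_growth_time = (world.t if world is not None else 0.0) + d.params.tau_g
        try:
            d.validate(check_nucleus_inside=False)
        except StructuralError:
            # concave arcs can lose simplicity during midpoint repopulation:
            # heal by equal-arclength resampling and re-placing the nucleus
            d.mem_pos = _resample_ring(d.mem_pos, d.n)
            d.nuc_pos = _place_daughter_nucleus(d.mem_pos, d.params.nucleus_radius)
            d.mem_vel = np.zeros_like(d.mem_pos)
            d.nuc_vel = np.zeros_like(d.nuc_pos)
            d.invalidate_caches()
            d.validate(check_nucleus_inside=False)
    if world is not None:
        world.remove_cell(cell.id)
        for d in daughters:
            world.add_cell(d)
    return tuple(daughters)


def _resample_ring(points: np.ndarray, m: int) -> np.ndarray:
    """Equal-arclength resampling of a (possibly invalid) closed ring via its
    repaired polygon outline; used to heal furrow kinks at abscission."""
    from shapely.geometry import LinearRing, Polygon
    from shapely import make_valid

    poly = Polygon(points)
    if not poly.is_valid:
        fixed = make_valid(poly)
        if fixed.geom_type == "GeometryCollection":
            polys = [g for g in fixed.geoms if g.geom_type == "Polygon"]
            fixed = max(polys, key=lambda g: g.area) if polys else poly.convex_hull
        if fixed.geom_type == "MultiPolygon":
            fixed = max(fixed.geoms, key=lambda g: g.area)
        poly = fixed
    ring = LinearRing(poly.exterior.coords)
    if not ring.is_ccw:
        ring = LinearRing(list(ring.coords)[::-1])
    fr = np.linspace(0.0, ring.length, m, endpoint=False)
    return np.array([ring.interpolate(f).coords[0] for f in fr])


def _place_daughter_nucleus(mem_pos: np.ndarray, nucleus_radius: float) -> np.ndarray:
    """Fresh nucleus ring inside a membrane ring, index-aligned so radial
    subunits stay radial; falls back to a regular ring for non-star shapes."""
    from shapely.geometry import Point as shapely_Point
    from shapely.geometry import Polygon

    poly = Polygon(mem_pos)
    center = mem_pos.mean(axis=0)
    if not poly.contains(shapely_Point(center)):
        center = np.asarray(poly.representative_point().coords[0])
    rel = mem_pos - center
    rel = rel / np.maximum(np.linalg.norm(rel, axis=1), 1e-12)[:, None]
    nuc_pos = center + nucleus_radius * rel
    if not Polygon(nuc_pos).is_valid or signed_area(nuc_pos) <= 0:
        from .geometry import regular_ring

        phase = math.atan2(*(mem_pos[0] - center)[::-1])
        nuc_pos = regular_ring(len(mem_pos), nucleus_radius, center, phase)
    return nuc_pos


def _extract_daughter(cell: Cell, order: np.ndarray, cid: int) -> Cell:
    m = len(order)
    p = cell.params
    last = order[-1]

    def closing(el: ElementArrays, kept_idx):
        """Ring elements along the arc plus one new closing subunit whose
        parameters average its two first neighbours."""
        k = np.append(el.k[kept_idx], 0.5 * (el.k[kept_idx[-1]] + el.k[(order[0] - 1) % cell.n]))
        eta = np.append(el.eta[kept_idx], 0.5 * (el.eta[kept_idx[-1]] + el.eta[(order[0] - 1) % cell.n]))
        L0 = np.append(el.L0[kept_idx], 0.5 * (el.L0[kept_idx[-1]] + el.L0[(order[0] - 1) % cell.n]))
        return ElementArrays(k, eta, L0)

    kept = order[:-1]  # elements i joining order[i] -> order[i+1]
    mem_pos = cell.mem_pos[order].copy()
    mem_vel = cell.mem_vel[order].copy()
    from shapely.geometry import Point as shapely_Point
    from shapely.geometry import Polygon

    if not Polygon(mem_pos).is_valid or signed_area(mem_pos) <= 0:
        mem_pos = _resample_ring(mem_pos, len(order))
        mem_vel = np.zeros_like(mem_pos)
    # the daughter nucleus is placed fresh: during anaphase the parent's
    # single nuclear ring is dragged into a hairpin, so each daughter gets a
    # new ring of its founder nucleus radius around its membrane centroid,
    # index-aligned with the membrane arc so radial subunits stay radial
    nuc_pos = _place_daughter_nucleus(mem_pos, p.nucleus_radius)
    d = Cell(
        cid,
        mem_pos,
        nuc_pos,
        p,
        mem_el=closing(cell.mem_el, kept),
        nucmem_el=closing(cell.nucmem_el, kept),
        radial=ElementArrays(
            cell.radial.k[order].copy(),
            cell.radial.eta[order].copy(),
            cell.radial.L0[order].copy(),
        ),
        chord=ElementArrays.uniform(
            m, p.k_chord, p.eta_chord, chord_rest_length(m, p.nucleus_radius)
        ),
        V_rest=cell.V_init_rest,
        nucleus_rest_radius=p.nucleus_radius,
    )
    d.mem_vel = mem_vel
    d.nuc_vel = np.zeros_like(nuc_pos)
    d.mem_drag = cell.mem_drag[order].copy()
    d.nuc_drag = cell.nuc_drag[order].copy()
    d.n0 = cell.n0
    d.division_enabled = cell.division_enabled
    d.growth_enabled = cell.growth_enabled
    d.P_in = cell.params.p_in
    _ = last
    return d


def _repopulate(cell: Cell, n_target: int) -> None:
    while cell.n < n_target:
        seg = segment_lengths(cell.mem_pos)
        cell.insert_node(int(np.argmax(seg)), grow=False)


def _renormalize_rest(cell: Cell) -> None:
    """Reset rest lengths to the founder-cell rest geometry (the daughter's
    rest volume is the founder rest volume)."""
    p = cell.params
    n = cell.n
    cell.mem_el.L0[:] = 2 * p.radius * np.sin(np.pi / n)
    cell.nucmem_el.L0[:] = 2 * p.nucleus_radius * np.sin(np.pi / n)
    cell.radial.L0[:] = p.radius - p.nucleus_radius
    cell.V_rest = cell.V_init_rest = 0.5 * n * p.radius**2 * np.sin(2 * np.pi / n)
    cell.nucleus_rest_radius = p.nucleus_radius
    cell.state = "quiescent"
    cell.growth_region = "growth"
    cell.mitosis = None
    cell.polarized = False
    cell.labels[:] = 0
    cell.invalidate_caches()


# ---------------------------------------------------------------- apoptosis
def start_apoptosis(cell: Cell, world: Optional[World] = None, p_env: float = 0.0) -> None:
    """Unilateral junction disassembly, rest-length collapse (division by the
    configured shrink factor), pressure differential removed.  Idempotent."""
    if cell.state == "apoptotic":
        return
    if world is not None:
        world.drop_bonds_of(cell.id)
        p_env = world.p_env
    s = cell.params.apoptosis_shrink
    for el in (cell.mem_el, cell.nucmem_el, cell.radial, cell.chord):
        if el is not None:
            el.L0 /= s
    cell.V_rest /= s * s
    cell.nucleus_rest_radius /= s
    cell.P_in = p_env
    cell.state = "apoptotic"
    cell.motile = False
    cell.mitosis = None
    cell.invalidate_caches()


def apoptosis_step(cell: Cell) -> None:
    """No active rule: the collapsed rest geometry shrinks the cell."""


def reap(world: World):
    """Delete apoptotic cells whose area fell below the minimal area."""
    dead = [
        cid
        for cid, c in world.cells.items()
        if c.state == "apoptotic"
        and abs(signed_area(c.mem_pos)) < c.params.min_area
    ]
    for cid in dead:
        world.remove_cell(cid)
    return dead


# ------------------------------------------------------------- polarization
def ecm_contact_map(world: World, cell: Cell) -> np.ndarray:
    """Membrane nodes holding at least one junction to an ECM chain."""
    mask = np.zeros(cell.n, dtype=bool)
    for (ra, rb) in world.bonds:
        for ref, other in ((ra, rb), (rb, ra)):
            if ref[0] == cell.id and other[1] == RING_ECM and ref[2] < cell.n:
                mask[ref[2]] = True
    return mask


def ecm_contact_maps(world: World):
    """Per-cell ECM contact masks in one pass over the bond set."""
    maps = {cid: np.zeros(c.n, dtype=bool) for cid, c in world.cells.items()}
    for (ra, rb) in world.bonds:
        for ref, other in ((ra, rb), (rb, ra)):
            if other[1] == RING_ECM and ref[0] in maps:
                mask = maps[ref[0]]
                if ref[2] < len(mask):
                    mask[ref[2]] = True
    return maps


def polarize(cell: Cell, contact_map: np.ndarray, apical_half_angle: float = np.pi / 3) -> None:
    """Label membrane domains from ECM contact.

    Contacting nodes become basal; nodes within ``apical_half_angle`` of the
    direction opposite the basal centroid become apical; the rest lateral.
    Without contact the cell is unpolarized and all labels cleared.
    """
    contact_map = np.asarray(contact_map, dtype=bool)
    if contact_map.sum() == 0:
        cell.polarized = False
        cell.labels[:] = 0
        return
    c = cell.centroid()
    basal_dir = cell.mem_pos[contact_map].mean(axis=0) - c
    nb = np.linalg.norm(basal_dir)
    basal_dir = basal_dir / nb if nb > 1e-12 else np.array([0.0, -1.0])
    rel = cell.mem_pos - c
    rel_n = rel / np.maximum(np.linalg.norm(rel, axis=1), 1e-12)[:, None]
    cosang = rel_n @ (-basal_dir)
    labels = np.full(cell.n, LABEL_CODES["lateral"], dtype=np.int8)
    labels[cosang >= np.cos(apical_half_angle)] = LABEL_CODES["apical"]
    labels[contact_map] = LABEL_CODES["basal"]
    cell.labels = labels
    cell.polarized = True


# ----------------------------------------------------------------- motility
@dataclass
class MotilityBlock:
    """Periodic protrusion/adhesion/contraction parameter cycling.

    Anterior and posterior regions swing between their initial and threshold
    radial rest lengths and drag coefficients in antiphase; the waveform is
    the half-wave-rectified envelope s(t) = max(0, sin(w t + phi))^2, which
    starts every region at its initial value, reaches the threshold a quarter
    period later (anterior first), and returns exactly to the initial values
    each full period.
    """

    omega: float
    anterior: np.ndarray           # bool mask over membrane nodes
    L0_init_a: np.ndarray
    L0_thresh_a: np.ndarray
    L0_init_p: np.ndarray
    L0_thresh_p: np.ndarray
    D_init_a: np.ndarray
    D_thresh_a: np.ndarray
    D_init_p: np.ndarray
    D_thresh_p: np.ndarray


def enable_motility(
    cell: Cell,
    direction=(1.0, 0.0),
    omega: float = 0.2,
    L0_factor_a: float = 1.5,
    L0_factor_p: float = 0.7,
    drag_factor_a: float = 0.2,
    drag_factor_p: float = 3.0,
) -> MotilityBlock:
    """Polarize the ring into anterior/posterior halves along ``direction``
    and attach a motility parameter block (thresholds as factors of the
    current values)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    rel = cell.mem_pos - cell.centroid()
    anterior = rel @ d > 0
    if anterior.sum() == 0 or (~anterior).sum() == 0:
        raise StructuralError("anterior/posterior split failed (degenerate ring)")
    cell.labels[anterior] = LABEL_CODES["anterior"]
    cell.labels[~anterior] = LABEL_CODES["posterior"]
    block = MotilityBlock(
        omega=omega,
        anterior=anterior,
        L0_init_a=cell.radial.L0[anterior].copy(),
        L0_thresh_a=cell.radial.L0[anterior] * L0_factor_a,
        L0_init_p=cell.radial.L0[~anterior].copy(),
        L0_thresh_p=cell.radial.L0[~anterior] * L0_factor_p,
        D_init_a=cell.mem_drag[anterior].copy(),
        D_thresh_a=cell.mem_drag[anterior] * drag_factor_a,
        D_init_p=cell.mem_drag[~anterior].copy(),
        D_thresh_p=cell.mem_drag[~anterior] * drag_factor_p,
    )
    cell.motile = True
    cell.motility = block
    return block


def motility_update(cell: Cell, t: float) -> None:
    """Advance the crawling parameter cycle to simulated time ``t``."""
    block = cell.motility
    if not cell.motile or block is None:
        raise StructuralError("cell has no motility block / labels")
    s_a = max(0.0, math.sin(block.omega * t)) ** 2
    s_p = max(0.0, math.sin(block.omega * t + math.pi)) ** 2
    ant = block.anterior
    cell.radial.L0[ant] = block.L0_init_a + (block.L0_thresh_a - block.L0_init_a) * s_a
    cell.radial.L0[~ant] = block.L0_init_p + (block.L0_thresh_p - block.L0_init_p) * s_p
    cell.mem_drag[ant] = block.D_init_a + (block.D_thresh_a - block.D_init_a) * s_a
    cell.mem_drag[~ant] = block.D_init_p + (block.D_thresh_p - block.D_init_p) * s_p
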