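"""Force accumulation, overdamped time integration, per-step scheduling.

The total force on a node decomposes into five terms: the intra-cellular
structural force, cell-cell interaction (adhesion + repulsion), cell-ECM
interaction, external fields, and mitosis forces.  Motion is overdamped
(low-Reynolds regime): node mass is book-kept but ignored and each node moves
with velocity F/D_eff.

Dashpot handling: every Voigt subunit's viscosity is lumped onto its two
endpoints' drag (D_eff = D + sum of incident eta), and forces are evaluated
from the springs alone.  This is exact for a single element relaxing against
a fixed wall (x(t) = x0 exp(-k t/(D + eta))) and is unconditionally stable in
the viscous term, which matters in the low-substrate-drag regime where an
explicit treatment of eta*dv diverges.  The lumping slightly over-damps
collective rigid motion; see the methods notes.

Per step, in order: (1) motility parameter cycling; (2) junction lifecycle
update; (3) force accumulation; (4) integration; (5) biological events
(growth attempts, division trigger / force phase / split, apoptosis triggers,
reaping, polarization); (6) scheduled outputs.  Deterministic given the
world's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, List, Optional

import numpy as np

from .adhesion import (
    Assembly,
    ForceMap,
    adhesion_forces,
    bond_eta_per_node,
    repulsion_forces,
    update_adhesions,
    zero_force_map,
)
from .cell import (
    Cell,
    cytoskeleton_forces,
    membrane_forces,
    nucleus_forces,
    pressure_forces,
)
from .elements import RING_ECM, RING_MEMBRANE, RING_NUCLEUS
from .processes import (
    add_growth_point,
    division_target_points,
    ecm_contact_maps,
    effective_growth_region,
    start_apoptosis,
    mitosis_forces,
    motility_update,
    furrow_closed,
    nuclear_separation,
    partition_cell,
    polarize,
    reap,
    select_division_axis,
    split_cell,
)
from .world import World


class SimulationUnstable(RuntimeError):
    pass


@dataclass
class EngineConfig:
    dt: float = 0.015                 # s
    n_steps: int = 1000
    integrator: str = "overdamped_euler"
    # force toggles
    pressure: bool = True
    repulsion: bool = True
    adhesion: bool = True
    external: bool = True
    mitosis: bool = True
    biology: bool = True
    bio_every: int = 1                # biology sub-scheduler cadence, steps
    polarization: bool = False        # label membrane domains from ECM contact
    apoptosis_predicate: Optional[Callable[[World, Cell], bool]] = None
    hooks: List[Callable[[World, list], None]] = dc_field(default_factory=list)
    # outputs
    frame_every: int = 0
    metrics_every: int = 0
    # safety
    instability_limit: float = 7.5    # um of motion per step that aborts
    check_stability: bool = True
    stop_when: Optional[Callable[[World], bool]] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.integrator != "overdamped_euler":
            raise ValueError(f"unknown integrator {self.integrator!r}")


@dataclass
class Event:
    step: int
    t: float
    kind: str
    cell: int
    info: tuple = ()

    def as_tuple(self):
        return (self.step, round(self.t, 9), self.kind, self.cell, self.info)


@dataclass
class RunResult:
    world: World
    events: List[Event]
    metrics: list                     # list of per-sample dict rows
    steps_done: int

    def metrics_frame(self):
        import pandas as pd

        return pd.DataFrame(self.metrics)


# ------------------------------------------------------------------- forces
def _membrane_drag(world: World, cell: Cell) -> np.ndarray:
    if world.substrate is not None and not cell.motile:
        return world.substrate(cell.mem_pos)
    return cell.mem_drag


def accumulate_forces(
    world: World,
    cfg: Optional[EngineConfig] = None,
    assembly: Optional[Assembly] = None,
) -> ForceMap:
    """Total force per node, keyed by (owner id, ring code).

    Forces on fixed (rigid-ECM) nodes are computed but never applied by the
    integrator.
    """
    cfg = cfg or EngineConfig()
    out = zero_force_map(world)
    for cid, cell in world.cells.items():
        f_mem = cytoskeleton_forces(cell, viscous=False) + membrane_forces(
            cell, viscous=False
        )
        if cfg.pressure:
            f_mem = f_mem + pressure_forces(cell, world.p_env)
        f_nuc = nucleus_forces(cell, viscous=False)
        if cfg.mitosis and cell.state == "mitotic" and cell.mitosis is not None:
            fm, fn = mitosis_forces(cell)
            f_mem = f_mem + fm
            f_nuc = f_nuc + fn
        if cfg.external and world.external_force is not None:
            f_mem = f_mem + world.external_force(cell.mem_pos)
        out[(cid, RING_MEMBRANE)] += f_mem
        out[(cid, RING_NUCLEUS)] += f_nuc
    for eid, chain in world.ecm_chains.items():
        out[(eid, RING_ECM)] += chain.chain_forces(viscous=False)
    if world.cells or world.ecm_chains:
        assembly = assembly or Assembly(world)
        flat = np.zeros_like(assembly.pos)
        if cfg.adhesion:
            adhesion_forces(world, assembly, out_flat=flat)
        if cfg.repulsion:
            repulsion_forces(world, world.adhesion_rule, assembly, out_flat=flat)
        for key, block in assembly.split(flat).items():
            out[key] += block
    return out


def world_force_total(forces: ForceMap) -> np.ndarray:
    return sum((f.sum(axis=0) for f in forces.values()), np.zeros(2))


def spring_potential(world: World) -> float:
    """Sum of elastic element energies 1/2 k (L - L0)^2 over the world, pN*um
    scale (nN*um); used as the mechanical energy proxy."""
    e = 0.0
    for cell in world.cells.values():
        for pos_a, pos_b, el in _cell_element_geometry(cell):
            L = np.linalg.norm(pos_b - pos_a, axis=1)
            e += float(np.sum(0.5 * el.k * (L - el.L0) ** 2))
    for chain in world.ecm_chains.values():
        ia, ib = chain.element_endpoints()
        L = np.linalg.norm(chain.pos[ib] - chain.pos[ia], axis=1)
        e += float(np.sum(0.5 * chain.k * (L - chain.L0) ** 2))
    keys, refs_a, refs_b, k, _, L0 = world.bond_endpoint_arrays()
    if keys:
        pa = np.array([world.pos_of(tuple(r)) for r in refs_a])
        pb = np.array([world.pos_of(tuple(r)) for r in refs_b])
        L = np.linalg.norm(pb - pa, axis=1)
        e += float(np.sum(0.5 * k * (L - L0) ** 2))
    return e


def _cell_element_geometry(cell: Cell):
    yield cell.mem_pos, np.roll(cell.mem_pos, -1, axis=0), cell.mem_el
    yield cell.nuc_pos, np.roll(cell.nuc_pos, -1, axis=0), cell.nucmem_el
    yield cell.mem_pos, cell.nuc_pos, cell.radial
    if cell.chord is not None:
        partner = (np.arange(cell.n) + cell.n // 2) % cell.n
        yield cell.nuc_pos, cell.nuc_pos[partner], cell.chord


# -------------------------------------------------------------- integration
def stability_bound(world: World) -> float:
    """min over elements of (min endpoint drag + eta)/k; dt must stay below."""
    bound = np.inf
    for cell in world.cells.values():
        dm = _membrane_drag(world, cell)
        dn = cell.nuc_drag
        pairs = (
            (np.minimum(dm, np.roll(dm, -1)), cell.mem_el),
            (np.minimum(dn, np.roll(dn, -1)), cell.nucmem_el),
            (np.minimum(dm, dn), cell.radial),
        )
        for dmin, el in pairs:
            bound = min(bound, float(np.min((dmin + el.eta) / el.k)))
        if cell.chord is not None:
            partner = (np.arange(cell.n) + cell.n // 2) % cell.n
            dmin = np.minimum(dn, dn[partner])
            bound = min(bound, float(np.min((dmin + cell.chord.eta) / cell.chord.k)))
    for chain in world.ecm_chains.values():
        if chain.rigid or chain.n_elements == 0:
            continue
        ia, ib = chain.element_endpoints()
        dmin = np.minimum(chain.drag[ia], chain.drag[ib])
        bound = min(bound, float(np.min((dmin + chain.eta) / chain.k)))
    return bound


def integrate_step(
    world: World,
    dt: float,
    forces: Optional[ForceMap] = None,
    cfg: Optional[EngineConfig] = None,
    assembly: Optional[Assembly] = None,
) -> float:
    """One overdamped Euler update; returns the largest node displacement, um.

    velocity = F_total / (D + sum of incident dashpot viscosities); fixed
    nodes do not move.  Raises on a zero effective drag for a free node.
    """
    cfg = cfg or EngineConfig(dt=dt)
    assembly = assembly or Assembly(world)
    if forces is None:
        forces = accumulate_forces(world, cfg, assembly)
    bond_eta = bond_eta_per_node(world, assembly)
    bond_eta_map = assembly.split(bond_eta) if len(assembly.pos) else {}
    max_disp = 0.0
    for cid, cell in world.cells.items():
        mem_eta, nuc_eta = cell.eta_sums()
        d_mem = _membrane_drag(world, cell) + mem_eta
        extra = bond_eta_map.get((cid, RING_MEMBRANE))
        if extra is not None:
            d_mem = d_mem + extra
        d_nuc = cell.nuc_drag + nuc_eta
        if np.any(d_mem <= 0) or np.any(d_nuc <= 0):
            raise ValueError(f"non-positive effective drag on cell {cid}")
        v_mem = forces[(cid, RING_MEMBRANE)] / d_mem[:, None]
        v_nuc = forces[(cid, RING_NUCLEUS)] / d_nuc[:, None]
        cell.mem_pos += v_mem * dt
        cell.nuc_pos += v_nuc * dt
        cell.mem_vel = v_mem
        cell.nuc_vel = v_nuc
        md = max(float(np.max(np.abs(v_mem))), float(np.max(np.abs(v_nuc)))) * dt
        max_disp = max(max_disp, md)
    for eid, chain in world.ecm_chains.items():
        if chain.rigid:
            chain.vel[:] = 0.0
            continue
        d = chain.drag + chain.eta_sums()
        extra = bond_eta_map.get((eid, RING_ECM))
        if extra is not None:
            d = d + extra
        if np.any(d <= 0):
            raise ValueError(f"non-positive effective drag on ECM {eid}")
        v = forces[(eid, RING_ECM)] / d[:, None]
        chain.pos += v * dt
        chain.vel = v
        if len(v):
            max_disp = max(max_disp, float(np.max(np.abs(v))) * dt)
    world.t += dt
    return max_disp


# ------------------------------------------------------------------ biology
def _biology(world: World, cfg: EngineConfig, step: int) -> List[Event]:
    events: List[Event] = []
    t = world.t

    if cfg.apoptosis_predicate is not None:
        for cid in sorted(world.cells):
            cell = world.cells[cid]
            if cell.state != "apoptotic" and cfg.apoptosis_predicate(world, cell):
                start_apoptosis(cell, world)
                events.append(Event(step, t, "apoptosis_start", cid))

    for cid in sorted(world.cells):
        cell = world.cells.get(cid)
        if cell is None or cell.state != "mitotic" or cell.mitosis is None:
            continue
        sep = nuclear_separation(cell)
        if sep >= cell.mitosis.L_div and (
            furrow_closed(cell) or sep >= 1.5 * cell.mitosis.L_div
        ):
            d1, d2 = split_cell(world, cell)
            events.append(Event(step, t, "division", cid, (d1.id, d2.id)))

    for cid in sorted(world.cells):
        cell = world.cells.get(cid)
        if cell is None or cell.state in ("mitotic", "apoptotic"):
            continue
        n_div = division_target_points(cell.n0)
        region = effective_growth_region(cell)
        if (
            cfg.mitosis
            and cell.division_enabled
            and cell.n >= n_div
            and cell.V_rest >= 2.0 * cell.V_init_rest * (1 - 1e-9)
            and region == "growth"
        ):
            axis = select_division_axis(cell)
            partition_cell(cell, axis)
            events.append(Event(step, t, "mitosis_start", cid))
            continue
        if cell.growth_enabled and t >= cell.next_growth_time:
            # +/-25% jitter on the attempt period desynchronizes lineage
            # clocks (division bursts would otherwise stay phase-locked)
            cell.next_growth_time = t + cell.params.tau_g * (
                0.75 + 0.5 * world.rng.random()
            )
            if region == "growth" and cell.n < n_div:
                k = add_growth_point(cell, world.rng, world)
                events.append(Event(step, t, "growth", cid, (k, cell.n)))

    if cfg.polarization and world.ecm_chains:
        contacts = ecm_contact_maps(world)
        for cid in sorted(world.cells):
            cell = world.cells[cid]
            if cell.state == "apoptotic":
                continue
            contact = contacts[cid]
            polarize(cell, contact)
            if contact.any():
                cell.ecm_contact_lost_since = None
            elif cell.ecm_contact_lost_since is None:
                cell.ecm_contact_lost_since = t

    for hook in cfg.hooks:
        hook(world, events)

    reaped = reap(world)
    for cid in reaped:
        events.append(Event(step, t, "reap", cid))
    return events


# ---------------------------------------------------------------------- run
def run(
    world: World,
    cfg: EngineConfig,
    frame_sink: Optional[Callable[[World, int], None]] = None,
    metrics_fn: Optional[Callable[[World], dict]] = None,
) -> RunResult:
    """Advance the world ``cfg.n_steps`` steps (or until ``cfg.stop_when``).

    Aborts with :class:`SimulationUnstable` if any node moves farther than
    ``cfg.instability_limit`` in one step.
    """
    if cfg.check_stability and (world.cells or world.ecm_chains):
        bound = stability_bound(world)
        if cfg.dt >= bound:
            raise ValueError(
                f"dt={cfg.dt} violates the stability bound {bound:.4g} "
                "(min over elements of (D_min + eta)/k)"
            )
    from . import _fast

    events: List[Event] = []
    metrics_rows: list = []
    steps_done = 0
    cache: Optional[_fast.MechCache] = None
    for step in range(cfg.n_steps):
        for cid in sorted(world.cells):
            cell = world.cells[cid]
            if cell.motile:
                motility_update(cell, world.t)
        if cache is None or cache.fp != _fast.fingerprint(world):
            cache = _fast.MechCache(world)
        pos = cache.gather_positions()
        assembly = cache.assembly(world, pos)
        if cfg.adhesion:
            update_adhesions(world, world.adhesion_rule, assembly)
        forces = _fast.compute_forces(world, cache, pos, cfg, assembly)
        max_disp = _fast.integrate(
            world, cache, pos, forces, cfg.dt, assembly, world.substrate
        )
        if max_disp > cfg.instability_limit:
            raise SimulationUnstable(
                f"step {step}: node displacement {max_disp:.3g} um exceeds "
                f"{cfg.instability_limit} um; reduce dt or stiffness"
            )
        if cfg.biology and step % cfg.bio_every == 0:
            events.extend(_biology(world, cfg, step))
        steps_done = step + 1
        if cfg.frame_every and step % cfg.frame_every == 0 and frame_sink:
            frame_sink(world, step)
        if cfg.metrics_every and step % cfg.metrics_every == 0 and metrics_fn:
            row = metrics_fn(world)
            row.update(step=step, t=world.t)
            metrics_rows.append(row)
        if cfg.stop_when is not None and cfg.stop_when(world):
            break
    return RunResult(world=world, events=events, metrics=metrics_rows, steps_done=steps_done)
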