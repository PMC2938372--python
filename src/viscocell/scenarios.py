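"""Named scenario builders reproducing the classic culture case studies.

Each scenario fully determines a constructible world from a small parameter
dict: monolayer growth from two founder cells under a substrate drag level,
epithelial sheets / cysts / inverted cysts on deformable ECM, a rigid ECM
line with a rectangular gap, matrix-thinning-driven budding, hollow-acinus
formation, and a single crawling cell.  Population scenarios discretize
cells into 20 membrane points (single-cell studies use 40) to keep
interactive run times short; ring size is a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .cell import Cell
from .config import D0, CellParams, EcmParams
from .ecm import SubstrateField, build_ecm
from .elements import RING_ECM
from .engine import EngineConfig
from .processes import enable_motility, start_apoptosis
from .world import World

SCENARIO_NAMES = (
    "single_cell",
    "monolayer",
    "ecm_line_epithelium",
    "ecm_hole_cyst",
    "inverted_cyst",
    "ecm_gap",
    "tensegrity_bud",
    "acinus",
    "crawling_cell",
)


@dataclass
class ScenarioSpec:
    name: str
    params: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")


def list_scenarios() -> Tuple[str, ...]:
    return SCENARIO_NAMES


def _merge(defaults: dict, overrides: dict) -> dict:
    p = dict(defaults)
    for k, v in overrides.items():
        if k not in p:
            raise ValueError(f"unknown scenario parameter {k!r}")
        p[k] = type(p[k])(v) if not isinstance(p[k], bool) else bool(float(v))
    return p


def _cell_params(p: dict) -> CellParams:
    return CellParams(
        n_points=int(p.get("n_points", 20)),
        radius=p.get("radius", 7.5),
        nucleus_radius=p.get("nucleus_radius", 3.0),
        tau_g=p.get("tau_g", 1.0),
    )


def _live_count(world: World) -> int:
    return sum(1 for c in world.cells.values() if c.state != "apoptotic")


def _auto_dt(world: World, requested: float, frac: float = 0.45, cap: float = 0.04) -> float:
    """Scenario time step: the requested value, or (requested == 0) a fixed
    fraction of the world's stability bound, capped for event resolution."""
    if requested > 0:
        return requested
    from .engine import stability_bound

    return min(cap, frac * stability_bound(world))


def loss_of_contact_predicate(T_apop: float):
    """Apoptosis trigger: sustained loss of ECM contact for T_apop seconds."""

    def pred(world: World, cell: Cell) -> bool:
        return (
            cell.ecm_contact_lost_since is not None
            and world.t - cell.ecm_contact_lost_since > T_apop
        )

    return pred


def ecm_remodel_hook(max_stretch: float = 1.8):
    """Split over-stretched ECM subunits (the matrix freely gains points)."""

    def hook(world: World, events) -> None:
        for eid in sorted(world.ecm_chains):
            ch = world.ecm_chains[eid]
            if ch.rigid or ch.n_elements == 0:
                continue
            ia, ib = ch.element_endpoints()
            L = np.linalg.norm(ch.pos[ib] - ch.pos[ia], axis=1)
            limit = max_stretch * ch.params.spacing
            for e in np.nonzero(L > limit)[0][::-1]:
                ch.split_element(int(e))
                world.remap_bonds_after_insert(eid, int(e), RING_ECM)

    return hook


class AcinusStaging:
    """Differentiation schedule of acinus formation.

    Phase 1: free proliferation until the colony reaches ``target_cells``.
    Phase 2 (differentiation): growth and division are suppressed; after
    ``settle_time`` seconds of polarization, every live cell without basal
    ECM contact (unpolarized interior cell) enters apoptosis, carving the
    lumen.  The run stops once no apoptotic cell remains and the structure
    has had ``post_time`` seconds to stabilize.
    """

    def __init__(self, target_cells: int, settle_time: float = 5.0, post_time: float = 20.0,
                 contact_fraction: float = 0.4):
        self.target = target_cells
        self.settle = settle_time
        self.post = post_time
        self.contact_fraction = contact_fraction
        self.differentiated_at: Optional[float] = None
        self.cleared_at: Optional[float] = None

    def hook(self, world: World, events) -> None:
        live = [c for c in world.cells.values() if c.state != "apoptotic"]
        if self.differentiated_at is None:
            # differentiation needs both a mature colony and an outer layer
            # actually facing the matrix (proliferation continues until the
            # cluster has grown out to the ECM)
            polarized = sum(1 for c in live if c.polarized)
            if len(live) >= self.target and polarized >= self.contact_fraction * len(live):
                self.differentiated_at = world.t
            else:
                return
        for c in live:
            c.growth_enabled = False
            c.division_enabled = False
        if world.t >= self.differentiated_at + self.settle:
            for c in live:
                if not c.polarized:
                    start_apoptosis(c, world)
        apoptotic = any(c.state == "apoptotic" for c in world.cells.values())
        if apoptotic:
            self.cleared_at = None   # a fresh death restarts the clearance clock
        elif (
            self.cleared_at is None
            and world.t > self.differentiated_at + self.settle
        ):
            self.cleared_at = world.t

    def stop(self, world: World) -> bool:
        if self.cleared_at is None or world.t <= self.cleared_at + self.post:
            return False
        # stable only when every survivor is a polarized, ECM-facing cell
        return all(
            c.polarized
            for c in world.cells.values()
            if c.state != "apoptotic"
        )


# ---------------------------------------------------------------- builders
def _build_single_cell(p: dict, seed: int):
    params = _cell_params({**p, "n_points": p["n_points"]})
    world = World(seed=seed)
    cell = Cell.build(params, cid=world.new_cell_id())
    cell.growth_enabled = bool(p["grow"])
    cell.division_enabled = bool(p["divide"])
    world.add_cell(cell)
    cfg = EngineConfig(dt=_auto_dt(world, p["dt"]), n_steps=int(p["steps"]))
    return world, cfg


def _build_monolayer(p: dict, seed: int):
    params = _cell_params(p)
    world = World(seed=seed, substrate=SubstrateField.uniform(p["drag"]))
    R = params.radius
    gap = params.L0_adhesion
    for cx in (-(R + gap / 2), R + gap / 2):
        world.add_cell(Cell.build(params, center=(cx, 0.0), cid=world.new_cell_id()))
    target = int(p["target_cells"])
    cfg = EngineConfig(
        dt=_auto_dt(world, p["dt"]),
        n_steps=int(p["steps"]),
        stop_when=lambda w: _live_count(w) >= target,
    )
    return world, cfg


def _seed_cells_on_line(world: World, params: CellParams, xs, y: float):
    for cx in xs:
        world.add_cell(Cell.build(params, center=(cx, y), cid=world.new_cell_id()))


def _build_ecm_line_epithelium(p: dict, seed: int):
    params = _cell_params(p)
    world = World(seed=seed)
    ecm = build_ecm("line", EcmParams(drag=p["ecm_drag"]), length=p["ecm_length"])
    world.add_ecm(ecm)
    y0 = params.radius + params.L0_adhesion
    _seed_cells_on_line(world, params, [0.0], y0)
    cfg = EngineConfig(
        dt=_auto_dt(world, p["dt"]),
        n_steps=int(p["steps"]),
        polarization=True,
        apoptosis_predicate=loss_of_contact_predicate(p["T_apop"]),
        stop_when=lambda w: _live_count(w) >= int(p["target_cells"]),
    )
    return world, cfg


def _build_ecm_hole_cyst(p: dict, seed: int):
    params = _cell_params(p)
    world = World(seed=seed)
    ecm = build_ecm("ring", EcmParams(drag=p["ecm_drag"]), radius=p["hole_radius"])
    world.add_ecm(ecm)
    cy = -(p["hole_radius"] - params.radius - params.L0_adhesion)
    world.add_cell(Cell.build(params, center=(0.0, cy), cid=world.new_cell_id()))
    cfg = EngineConfig(
        dt=_auto_dt(world, p["dt"]),
        n_steps=int(p["steps"]),
        polarization=True,
        apoptosis_predicate=loss_of_contact_predicate(p["T_apop"]),
        hooks=[ecm_remodel_hook()],
        stop_when=lambda w: _live_count(w) >= int(p["target_cells"]),
    )
    return world, cfg


def _build_inverted_cyst(p: dict, seed: int):
    params = _cell_params(p)
    world = World(seed=seed)
    ecm = build_ecm("ring", EcmParams(drag=p["ecm_drag"]), radius=p["ecm_radius"])
    world.add_ecm(ecm)
    cy = p["ecm_radius"] + params.radius + params.L0_adhesion
    world.add_cell(Cell.build(params, center=(0.0, cy), cid=world.new_cell_id()))
    cfg = EngineConfig(
        dt=_auto_dt(world, p["dt"]),
        n_steps=int(p["steps"]),
        polarization=True,
        apoptosis_predicate=loss_of_contact_predicate(p["T_apop"]),
        stop_when=lambda w: _live_count(w) >= int(p["target_cells"]),
    )
    return world, cfg


def _build_ecm_gap(p: dict, seed: int):
    params = _cell_params(p)
    world = World(seed=seed)
    W = p["gap_width_R"] * params.radius
    ecm = build_ecm(
        "line_with_gap",
        EcmParams(),
        length=p["ecm_length"],
        gap_width=W,
        gap_depth=p["gap_depth_R"] * params.radius,
        rigid=True,
    )
    world.add_ecm(ecm)
    y0 = params.radius + params.L0_adhesion
    xs = [
        -W / 2 - 3 * params.radius - params.L0_adhesion,
        -W / 2 - params.radius,
    ]
    _seed_cells_on_line(world, params, xs, y0)
    cfg = EngineConfig(
        dt=_auto_dt(world, p["dt"]),
        n_steps=int(p["steps"]),
        polarization=True,
        stop_when=lambda w: _live_count(w) >= int(p["target_cells"]),
    )
    return world, cfg


def _build_tensegrity_bud(p: dict, seed: int):
    params = _cell_params(p)
    world = World(seed=seed)
    ecm = build_ecm(
        "line",
        EcmParams(drag=p["ecm_drag"]),
        length=p["ecm_length"],
        drag_dip_depth=p["dip_depth"],
        drag_dip_sigma=p["dip_sigma"],
    )
    # anchored shoulders: the matrix is held by surrounding tissue away from
    # the thinned centre, so only the central region can be driven downward
    shoulders = np.abs(ecm.pos[:, 0]) > 0.2 * p["ecm_length"]
    ecm.drag[shoulders] *= 1000.0
    world.add_ecm(ecm)
    n_cells = int(p["n_cells"])
    pitch = 2 * params.radius + params.L0_adhesion
    xs = (np.arange(n_cells) - (n_cells - 1) / 2) * pitch
    _seed_cells_on_line(world, params, xs, params.radius + params.L0_adhesion)
    cfg = EngineConfig(
        dt=_auto_dt(world, p["dt"]),
        n_steps=int(p["steps"]),
        polarization=True,
        hooks=[ecm_remodel_hook()],
    )
    return world, cfg


def _build_acinus(p: dict, seed: int):
    params = _cell_params(p)
    world = World(seed=seed)
    ecm = build_ecm(
        "ring",
        EcmParams(k=p["ecm_k"], drag=p["ecm_drag"]),
        radius=p["ecm_radius"],
    )
    world.add_ecm(ecm)
    world.add_cell(Cell.build(params, cid=world.new_cell_id()))
    staging = AcinusStaging(
        int(p["target_cells"]), settle_time=p["settle_time"], post_time=p["post_time"],
        contact_fraction=0.75,
    )
    cfg = EngineConfig(
        dt=_auto_dt(world, p["dt"]),
        n_steps=int(p["steps"]),
        polarization=True,
        bio_every=5,
        hooks=[ecm_remodel_hook(), staging.hook],
        stop_when=staging.stop,
    )
    return world, cfg


def _build_crawling_cell(p: dict, seed: int):
    params = _cell_params({**p, "n_points": p["n_points"]})
    world = World(seed=seed, substrate=SubstrateField.uniform(p["drag"]))
    cell = Cell.build(params, cid=world.new_cell_id())
    cell.growth_enabled = False
    cell.division_enabled = False
    cell.mem_drag[:] = p["drag"]
    enable_motility(cell, direction=(1.0, 0.0), omega=p["omega"])
    world.add_cell(cell)
    cfg = EngineConfig(dt=_auto_dt(world, p["dt"]), n_steps=int(p["steps"]))
    return world, cfg


_DEFAULTS: Dict[str, dict] = {
    "single_cell": dict(n_points=40, radius=7.5, nucleus_radius=3.0, grow=False,
                        divide=False, dt=0.0, steps=2000, tau_g=1.0),
    "monolayer": dict(n_points=20, radius=7.5, nucleus_radius=3.0, drag=D0,
                      target_cells=60, dt=0.0, steps=60000, tau_g=1.0),
    "ecm_line_epithelium": dict(n_points=20, radius=7.5, nucleus_radius=3.0,
                                ecm_length=150.0, ecm_drag=5.0, T_apop=10.0,
                                target_cells=8, dt=0.0, steps=20000, tau_g=1.0),
    "ecm_hole_cyst": dict(n_points=20, radius=7.5, nucleus_radius=3.0,
                          hole_radius=25.0, ecm_drag=5.0, T_apop=10.0,
                          target_cells=8, dt=0.0, steps=20000, tau_g=1.0),
    "inverted_cyst": dict(n_points=20, radius=7.5, nucleus_radius=3.0,
                          ecm_radius=12.0, ecm_drag=5.0, T_apop=10.0,
                          target_cells=8, dt=0.0, steps=20000, tau_g=1.0),
    "ecm_gap": dict(n_points=20, radius=7.5, nucleus_radius=3.0, ecm_length=120.0,
                    gap_width_R=2.0, gap_depth_R=3.0, target_cells=10,
                    dt=0.0, steps=20000, tau_g=1.0),
    "tensegrity_bud": dict(n_points=20, radius=7.5, nucleus_radius=3.0,
                           ecm_length=80.0, ecm_drag=5.0, dip_depth=0.9,
                           dip_sigma=8.0, n_cells=4, dt=0.0, steps=4000, tau_g=1.0),
    "acinus": dict(n_points=20, radius=7.5, nucleus_radius=3.0, ecm_radius=24.0,
                   ecm_k=4.0, ecm_drag=8.0, target_cells=11, settle_time=8.0,
                   post_time=20.0, dt=0.0, steps=160000, tau_g=1.0),
    "crawling_cell": dict(n_points=20, radius=7.5, nucleus_radius=3.0, drag=2.0,
                          omega=0.2, dt=0.0, steps=4000),
}

_BUILDERS = {
    "single_cell": _build_single_cell,
    "monolayer": _build_monolayer,
    "ecm_line_epithelium": _build_ecm_line_epithelium,
    "ecm_hole_cyst": _build_ecm_hole_cyst,
    "inverted_cyst": _build_inverted_cyst,
    "ecm_gap": _build_ecm_gap,
    "tensegrity_bud": _build_tensegrity_bud,
    "acinus": _build_acinus,
    "crawling_cell": _build_crawling_cell,
}


def make_world(spec: ScenarioSpec) -> Tuple[World, EngineConfig]:
    """Build a named scenario's initial world and engine configuration."""
    p = _merge(_DEFAULTS[spec.name], spec.params)
    world, cfg = _BUILDERS[spec.name](p, spec.seed)
    for a in world.cells.values():
        for b in world.cells.values():
            if a.id < b.id and a.membrane_polygon().intersects(b.membrane_polygon()):
                raise ValueError("initial cells overlap")
    return world, cfg


# ------------------------------------------------------------- gap analysis
def gap_regime_classifier(final_world: World, W: float, R: float) -> str:
    """Classify an ECM-gap outcome from the final geometry.

    Regimes: ``not_lined`` (no cell entered the notch), ``entry_blocked``
    (a single cell wedged in the mouth), ``entrapped`` (cells inside but the
    notch floor is not fully covered), ``lined`` (walls and floor covered by
    cell contacts).
    """
    chains = list(final_world.ecm_chains.values())
    if not chains:
        raise ValueError("no ECM in world")
    ch = chains[0]
    floor_y = float(ch.pos[:, 1].min())
    mouth_y = float(ch.pos[:, 1].max())
    half = W / 2.0
    live = [c for c in final_world.cells.values() if c.state != "apoptotic"]
    inside = [
        c
        for c in live
        if abs(c.centroid()[0]) < half + R / 2 and c.centroid()[1] < mouth_y
    ]
    if not inside:
        return "not_lined"

    rule = final_world.adhesion_rule
    all_nodes = (
        np.concatenate([c.mem_pos for c in live], axis=0)
        if live
        else np.zeros((0, 2))
    )

    def covered(samples: np.ndarray) -> np.ndarray:
        if len(all_nodes) == 0:
            return np.zeros(len(samples), dtype=bool)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(all_nodes).query(samples)
        return d < 2.0 * rule.d_a

    ny = max(4, int((mouth_y - floor_y) / 2))
    nx = max(4, int(W / 2))
    floor = np.stack(
        [np.linspace(-half, half, nx), np.full(nx, floor_y)], axis=1
    )
    wall_y = np.linspace(floor_y, mouth_y, ny)
    walls = np.concatenate(
        [
            np.stack([np.full(ny, -half), wall_y], axis=1),
            np.stack([np.full(ny, half), wall_y], axis=1),
        ]
    )
    floor_full = bool(covered(floor).all())
    walls_full = bool(covered(walls).all())
    if floor_full and walls_full:
        return "lined"
    if len(inside) == 1:
        return "entry_blocked"
    return "entrapped"


def max_ecm_deflection(world: World, reference_y: float = 0.0) -> float:
    """Largest downward ECM displacement from the initial line height, um."""
    m = 0.0
    for ch in world.ecm_chains.values():
        m = max(m, float(reference_y - ch.pos[:, 1].min()))
    return m
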