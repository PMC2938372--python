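"""Plain-text frame serialization (versioned, diffable, round-trip exact).

A frame is a single TSV-sectioned text document holding the node, element,
cell, ECM and bond tables plus the world header.  Floats are written with 17
significant digits so a read-back world reproduces positions to full double
precision.  A trailing ``[end]`` sentinel makes truncation detectable.

Custom substrate fields and scenario hooks are run-time objects and do not
round-trip; uniform substrate fields are reconstructed from their label.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, TextIO, Union

import numpy as np

from .cell import Cell, ElementArrays
from .config import AdhesionRule, CellParams, EcmParams
from .ecm import ECMChain, SubstrateField
from .elements import LABELS, LABEL_CODES
from .processes import DivisionAxis, MitosisState
from .world import Bond, World

FORMAT_VERSION = 1

_CELL_COLS = (
    "id n n0 state growth_region polarized motile division_enabled growth_enabled "
    "V_rest V_init_rest nucleus_rest_radius P_in c_s c_g next_growth_time "
    "contact_lost_since params mitosis"
).split()
_NODE_COLS = "owner ring index x y vx vy drag mass label fixed".split()
_ELEM_COLS = "category a_owner a_ring a_idx b_owner b_ring b_idx k eta L0".split()
_BOND_COLS = "a_owner a_ring a_idx b_owner b_ring b_idx k eta L0 created_at".split()
_ECM_COLS = "id n closed rigid params".split()


class FrameParseError(ValueError):
    def __init__(self, msg: str, line: Optional[int] = None):
        super().__init__(f"line {line}: {msg}" if line is not None else msg)
        self.line = line


def _f(x: float) -> str:
    return format(float(x), ".17g")


def _open(sink, mode: str):
    if hasattr(sink, "write") or hasattr(sink, "read"):
        return sink, False
    return open(Path(sink), mode), True


# -------------------------------------------------------------------- write
def write_frame(world: World, sink: Union[str, Path, TextIO]) -> None:
    fh, close = _open(sink, "w")
    try:
        w = fh.write
        w(f"# viscocell-frame {FORMAT_VERSION}\n")
        w(f"# t {_f(world.t)}\n")
        w(f"# p_env {_f(world.p_env)}\n")
        w(f"# seed {world.seed}\n")
        sub = world.substrate.label if world.substrate is not None else "none"
        w(f"# substrate {sub}\n")
        r = world.adhesion_rule
        w(
            f"# adhesion {_f(r.d_a)} {_f(r.d_r)} {_f(r.d_rep)} {_f(r.k_rep)} "
            f"{int(r.one_bond_per_pair)}\n"
        )

        w("[cells]\n")
        w("\t".join(_CELL_COLS) + "\n")
        for cid in sorted(world.cells):
            c = world.cells[cid]
            mit = "-"
            if c.mitosis is not None:
                s = c.mitosis
                mit = json.dumps(
                    dict(
                        point=list(s.axis.point),
                        direction=list(s.axis.direction),
                        u=list(s.u),
                        anchor=int(s.anchor_index),
                        order_a=[int(i) for i in s.order_a],
                        order_b=[int(i) for i in s.order_b],
                        F_div_n=s.F_div_n,
                        F_div_m=s.F_div_m,
                        L_div=s.L_div,
                    )
                )
            row = [
                str(c.id), str(c.n), str(c.n0), c.state, c.growth_region,
                str(int(c.polarized)), str(int(c.motile)),
                str(int(c.division_enabled)), str(int(c.growth_enabled)),
                _f(c.V_rest), _f(c.V_init_rest), _f(c.nucleus_rest_radius),
                _f(c.P_in), _f(c.c_s), _f(c.c_g), _f(c.next_growth_time),
                "-" if c.ecm_contact_lost_since is None else _f(c.ecm_contact_lost_since),
                json.dumps(asdict(c.params)), mit,
            ]
            w("\t".join(row) + "\n")

        w("[ecm]\n")
        w("\t".join(_ECM_COLS) + "\n")
        for eid in sorted(world.ecm_chains):
            ch = world.ecm_chains[eid]
            w(
                "\t".join(
                    [str(ch.id), str(ch.n), str(int(ch.closed)), str(int(ch.rigid)),
                     json.dumps(asdict(ch.params))]
                )
                + "\n"
            )

        w("[nodes]\n")
        w("\t".join(_NODE_COLS) + "\n")
        for owner in [world.cells[c] for c in sorted(world.cells)] + [
            world.ecm_chains[e] for e in sorted(world.ecm_chains)
        ]:
            for node in owner.iter_nodes():
                w(
                    "\t".join(
                        [
                            str(node.owner), node.ring, str(node.index),
                            _f(node.position[0]), _f(node.position[1]),
                            _f(node.velocity[0]), _f(node.velocity[1]),
                            _f(node.drag), _f(node.mass), node.label,
                            str(int(node.fixed)),
                        ]
                    )
                    + "\n"
                )

        w("[elements]\n")
        w("\t".join(_ELEM_COLS) + "\n")
        for owner in [world.cells[c] for c in sorted(world.cells)] + [
            world.ecm_chains[e] for e in sorted(world.ecm_chains)
        ]:
            for el in owner.iter_elements():
                w(
                    "\t".join(
                        [
                            el.category,
                            str(el.a[0]), str(el.a[1]), str(el.a[2]),
                            str(el.b[0]), str(el.b[1]), str(el.b[2]),
                            _f(el.k), _f(el.eta), _f(el.L0),
                        ]
                    )
                    + "\n"
                )

        w("[bonds]\n")
        w("\t".join(_BOND_COLS) + "\n")
        for key in sorted(world.bonds):
            b = world.bonds[key]
            (ao, ar, ai), (bo, br, bi) = key
            w(
                "\t".join(
                    [str(ao), str(ar), str(ai), str(bo), str(br), str(bi),
                     _f(b.k), _f(b.eta), _f(b.L0), _f(b.created_at)]
                )
                + "\n"
            )
        w("[end]\n")
    finally:
        if close:
            fh.close()


# --------------------------------------------------------------------- read
def read_frame(source: Union[str, Path, TextIO]) -> World:
    fh, close = _open(source, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    if not lines or not lines[0].startswith("# viscocell-frame"):
        raise FrameParseError("missing frame signature", 1)
    if lines[-1].strip() != "[end]":
        raise FrameParseError("truncated frame (missing [end] sentinel)", len(lines))

    header: Dict[str, str] = {}
    sections: Dict[str, List[List[str]]] = {}
    section = None
    for ln, raw in enumerate(lines[1:], start=2):
        if raw.startswith("# "):
            key, _, val = raw[2:].partition(" ")
            header[key] = val
            continue
        m = re.fullmatch(r"\[(\w+)\]", raw.strip())
        if m:
            section = m.group(1)
            sections[section] = []
            continue
        if section is None:
            raise FrameParseError(f"data before any section: {raw!r}", ln)
        sections[section].append(raw.split("\t"))

    for required in ("cells", "ecm", "nodes", "elements", "bonds"):
        if required not in sections:
            raise FrameParseError(f"missing [{required}] section")

    def table(name: str, cols: List[str]):
        rows = sections[name]
        if not rows:
            raise FrameParseError(f"[{name}] missing header row")
        if rows[0] != cols:
            raise FrameParseError(f"[{name}] unexpected columns {rows[0]!r}")
        for r in rows[1:]:
            if len(r) != len(cols):
                raise FrameParseError(f"[{name}] row has {len(r)} fields, expected {len(cols)}")
        return [dict(zip(cols, r)) for r in rows[1:]]

    sub = None
    sub_label = header.get("substrate", "none")
    m = re.fullmatch(r"uniform\(([-0-9.eE+]+)\)", sub_label)
    if m:
        sub = SubstrateField.uniform(float(m.group(1)))
    ad = header.get("adhesion", "").split()
    rule = (
        AdhesionRule(
            d_a=float(ad[0]), d_r=float(ad[1]), d_rep=float(ad[2]),
            k_rep=float(ad[3]), one_bond_per_pair=bool(int(ad[4])),
        )
        if len(ad) == 5
        else AdhesionRule()
    )
    world = World(
        p_env=float(header.get("p_env", 0.0)),
        adhesion_rule=rule,
        substrate=sub,
        seed=int(header.get("seed", 0)),
    )
    world.t = float(header.get("t", 0.0))

    nodes = table("nodes", _NODE_COLS)
    elems = table("elements", _ELEM_COLS)

    def owner_nodes(owner: int, ring: str):
        rows = [r for r in nodes if int(r["owner"]) == owner and r["ring"] == ring]
        rows.sort(key=lambda r: int(r["index"]))
        pos = np.array([[float(r["x"]), float(r["y"])] for r in rows])
        vel = np.array([[float(r["vx"]), float(r["vy"])] for r in rows])
        drag = np.array([float(r["drag"]) for r in rows])
        mass = np.array([float(r["mass"]) for r in rows])
        labels = np.array([LABEL_CODES[r["label"]] for r in rows], dtype=np.int8)
        return pos, vel, drag, mass, labels

    def owner_elements(owner: int, category: str) -> Optional[ElementArrays]:
        rows = [
            r for r in elems if int(r["a_owner"]) == owner and r["category"] == category
        ]
        if not rows:
            return None
        rows.sort(key=lambda r: int(r["a_idx"]))
        return ElementArrays(
            np.array([float(r["k"]) for r in rows]),
            np.array([float(r["eta"]) for r in rows]),
            np.array([float(r["L0"]) for r in rows]),
        )

    for row in table("cells", _CELL_COLS):
        cid = int(row["id"])
        params = CellParams(**json.loads(row["params"]))
        mem_pos, mem_vel, mem_drag, mem_mass, labels = owner_nodes(cid, "membrane")
        nuc_pos, nuc_vel, nuc_drag, nuc_mass, _ = owner_nodes(cid, "nucleus")
        cell = Cell(
            cid, mem_pos, nuc_pos, params,
            mem_el=owner_elements(cid, "membrane"),
            nucmem_el=owner_elements(cid, "nuclear_membrane"),
            radial=owner_elements(cid, "radial"),
            chord=owner_elements(cid, "nuclear_chord"),
            V_rest=float(row["V_rest"]),
            nucleus_rest_radius=float(row["nucleus_rest_radius"]),
        )
        cell.V_init_rest = float(row["V_init_rest"])
        cell.mem_vel, cell.nuc_vel = mem_vel, nuc_vel
        cell.mem_drag, cell.nuc_drag = mem_drag, nuc_drag
        cell.mem_mass, cell.nuc_mass = mem_mass, nuc_mass
        cell.labels = labels
        cell.P_in = float(row["P_in"])
        cell.c_s, cell.c_g = float(row["c_s"]), float(row["c_g"])
        cell.state = row["state"]
        cell.growth_region = row["growth_region"]
        cell.polarized = bool(int(row["polarized"]))
        cell.motile = bool(int(row["motile"]))
        cell.division_enabled = bool(int(row["division_enabled"]))
        cell.growth_enabled = bool(int(row["growth_enabled"]))
        cell.n0 = int(row["n0"])
        cell.next_growth_time = float(row["next_growth_time"])
        cell.ecm_contact_lost_since = (
            None if row["contact_lost_since"] == "-" else float(row["contact_lost_since"])
        )
        if row["mitosis"] != "-":
            m = json.loads(row["mitosis"])
            order_a = np.array(m["order_a"], dtype=np.int64)
            group_a = np.zeros(cell.n, dtype=bool)
            group_a[order_a] = True
            cell.mitosis = MitosisState(
                axis=DivisionAxis(np.array(m["point"]), np.array(m["direction"])),
                group_a=group_a,
                anchor_index=int(m["anchor"]),
                u=np.array(m["u"]),
                F_div_n=float(m["F_div_n"]),
                F_div_m=float(m["F_div_m"]),
                L_div=float(m["L_div"]),
                order_a=order_a,
                order_b=np.array(m["order_b"], dtype=np.int64),
            )
        world.add_cell(cell)

    for row in table("ecm", _ECM_COLS):
        eid = int(row["id"])
        params = EcmParams(**json.loads(row["params"]))
        pos, vel, drag, _, _ = owner_nodes(eid, "ecm")
        chain = ECMChain(
            pos, params,
            closed=bool(int(row["closed"])),
            rigid=bool(int(row["rigid"])),
            drag_profile=drag,
            eid=eid,
        )
        chain.vel = vel
        el = owner_elements(eid, "ecm_chain")
        if el is not None:
            chain.k, chain.eta, chain.L0 = el.k, el.eta, el.L0
        world.ecm_chains[eid] = chain

    for row in table("bonds", _BOND_COLS):
        ref_a = (int(row["a_owner"]), int(row["a_ring"]), int(row["a_idx"]))
        ref_b = (int(row["b_owner"]), int(row["b_ring"]), int(row["b_idx"]))
        world.add_bond(
            ref_a, ref_b,
            Bond(float(row["k"]), float(row["eta"]), float(row["L0"]),
                 created_at=float(row["created_at"])),
        )
    return world


# ------------------------------------------------------------ other outputs
def write_events(events, sink: Union[str, Path, TextIO]) -> None:
    fh, close = _open(sink, "w")
    try:
        fh.write("step\tt\tkind\tcell\tinfo\n")
        for e in events:
            fh.write(f"{e.step}\t{_f(e.t)}\t{e.kind}\t{e.cell}\t{json.dumps(list(e.info))}\n")
    finally:
        if close:
            fh.close()


def write_metrics(rows, sink: Union[str, Path, TextIO]) -> None:
    import pandas as pd

    df = pd.DataFrame(rows)
    if hasattr(sink, "write"):
        df.to_csv(sink, sep="\t", index=False)
    else:
        df.to_csv(Path(sink), sep="\t", index=False)
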