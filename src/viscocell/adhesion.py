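"""Cell-cell and cell-ECM coupling: junction lifecycle and elastic repulsion.

Adhesion bonds are Voigt subunits created between membrane/ECM nodes of
different owners once they come closer than ``d_a`` and ruptured only beyond
``d_r`` > ``d_a`` (hysteresis).  Bond parameters are the series combination of
the two owners' attachment templates.  Short-range repulsion is a linear ramp
k_rep*(d_rep - d) on each membrane node whose nearest foreign surface point
is closer than ``d_rep``, directed along the inward normal of the node's own
membrane, with the reaction spread barycentrically over the nearest foreign
segment so that the world force total is conserved.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .config import AdhesionRule
from .elements import (
    RING_ECM,
    RING_MEMBRANE,
    combine_adhesion_params,
    elastic_pair_forces,
    pair_forces,
)
from .geometry import outward_normals, points_segments_distance
from .world import Bond, World, bond_key

ForceMap = Dict[Tuple[int, int], np.ndarray]  # (owner id, ring code) -> (n, 2)


class Assembly:
    """Flat per-step view of the interaction-eligible nodes (membranes + ECM).

    Owners appear in ascending-id blocks (cells first, then ECM chains whose
    ids are offset above all cell ids), so flat indices are recovered with a
    single searchsorted.
    """

    def __init__(self, world: World, _precomputed=None) -> None:
        self.world = world
        if _precomputed is not None:
            (self.pos, self.owner, self.ring, self.idx,
             self.block_ids, self.block_starts) = _precomputed
            self._tree: Optional[cKDTree] = None
            return
        self.pos, self.owner, self.ring, self.idx = world.interaction_nodes()
        block_ids = []
        block_starts = []
        start = 0
        for cid in sorted(world.cells):
            block_ids.append(cid)
            block_starts.append(start)
            start += world.cells[cid].n
        for eid in sorted(world.ecm_chains):
            block_ids.append(eid)
            block_starts.append(start)
            start += world.ecm_chains[eid].n
        self.block_ids = np.asarray(block_ids, dtype=np.int64)
        self.block_starts = np.asarray(block_starts, dtype=np.int64)
        self._tree = None

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.pos)
        return self._tree

    def flat_of(self, refs: np.ndarray) -> np.ndarray:
        """Flat row of each (owner, ring, index) ref (membrane/ECM only)."""
        if len(refs) == 0:
            return np.zeros(0, dtype=np.int64)
        blocks = np.searchsorted(self.block_ids, refs[:, 0])
        return self.block_starts[blocks] + refs[:, 2]

    def split(self, flat_array: np.ndarray) -> ForceMap:
        """Split a flat per-node array back into per-owner blocks."""
        out: ForceMap = {}
        for i, oid in enumerate(self.block_ids):
            a = self.block_starts[i]
            b = (
                self.block_starts[i + 1]
                if i + 1 < len(self.block_starts)
                else len(self.pos)
            )
            ring = RING_ECM if oid in self.world.ecm_chains else RING_MEMBRANE
            out[(int(oid), ring)] = flat_array[a:b]
        return out


def zero_force_map(world: World) -> ForceMap:
    from .elements import RING_NUCLEUS

    out: ForceMap = {}
    for cid, cell in world.cells.items():
        out[(cid, RING_MEMBRANE)] = np.zeros((cell.n, 2))
        out[(cid, RING_NUCLEUS)] = np.zeros((cell.n, 2))
    for eid, chain in world.ecm_chains.items():
        out[(eid, RING_ECM)] = np.zeros((chain.n, 2))
    return out


def _adhesion_template(world: World, oid: int):
    owner = world.owner_of(oid)
    return owner.params  # CellParams and EcmParams both expose *_adhesion


def update_adhesions(
    world: World,
    rule: Optional[AdhesionRule] = None,
    assembly: Optional[Assembly] = None,
):
    """One junction-lifecycle sweep; returns (created_keys, ruptured_keys).

    Creation: any membrane/ECM node pair of different owners closer than
    ``d_a`` with no existing bond gets one.  Rupture: any bond stretched
    beyond ``d_r`` is removed, as are all bonds of apoptotic cells
    (unilateral disruption).  Bonds between d_a and d_r persist.
    """
    rule = rule or world.adhesion_rule
    assembly = assembly or Assembly(world)

    ruptured = []
    keys, refs_a, refs_b, _, _, _ = world.bond_endpoint_arrays()
    if keys:
        pa = assembly.pos[assembly.flat_of(refs_a)]
        pb = assembly.pos[assembly.flat_of(refs_b)]
        L = np.linalg.norm(pb - pa, axis=1)
        drop = L > rule.d_r
        apoptotic = [cid for cid, c in world.cells.items() if c.state == "apoptotic"]
        if apoptotic:
            ap = np.asarray(apoptotic, dtype=np.int64)
            drop |= np.isin(refs_a[:, 0], ap) | np.isin(refs_b[:, 0], ap)
        ruptured = [keys[i] for i in np.nonzero(drop)[0]]
        world.remove_bonds(ruptured)

    created = []
    if len(assembly.pos):
        pairs = assembly.tree.query_pairs(rule.d_a, output_type="ndarray")
        if len(pairs):
            oa = assembly.owner[pairs[:, 0]]
            ob = assembly.owner[pairs[:, 1]]
            keep = oa != ob
            # no ECM-ECM junctions; no new bonds on apoptotic cells
            keep &= ~(
                (assembly.ring[pairs[:, 0]] == RING_ECM)
                & (assembly.ring[pairs[:, 1]] == RING_ECM)
            )
            apoptotic = [
                cid for cid, c in world.cells.items() if c.state == "apoptotic"
            ]
            if apoptotic:
                ap = np.asarray(apoptotic, dtype=np.int64)
                keep &= ~(np.isin(oa, ap) | np.isin(ob, ap))
            pairs = pairs[keep]
            if len(pairs) and rule.one_bond_per_pair and world.bonds:
                # drop candidates that already hold a bond (vectorised)
                _, refs_a, refs_b, _, _, _ = world.bond_endpoint_arrays()
                ea = assembly.flat_of(refs_a)
                eb = assembly.flat_of(refs_b)
                n_flat = np.int64(len(assembly.pos))
                packed_existing = np.minimum(ea, eb) * n_flat + np.maximum(ea, eb)
                packed = (
                    np.minimum(pairs[:, 0], pairs[:, 1]) * n_flat
                    + np.maximum(pairs[:, 0], pairs[:, 1])
                )
                pairs = pairs[~np.isin(packed, packed_existing)]
            for fa, fb in pairs:
                ref_a = (
                    int(assembly.owner[fa]),
                    int(assembly.ring[fa]),
                    int(assembly.idx[fa]),
                )
                ref_b = (
                    int(assembly.owner[fb]),
                    int(assembly.ring[fb]),
                    int(assembly.idx[fb]),
                )
                key = bond_key(ref_a, ref_b)
                if key in world.bonds:
                    continue
                ta = _adhesion_template(world, ref_a[0])
                tb = _adhesion_template(world, ref_b[0])
                k, eta = combine_adhesion_params(ta, tb)
                L0 = 0.5 * (ta.L0_adhesion + tb.L0_adhesion)
                world.add_bond(ref_a, ref_b, Bond(k, eta, L0, created_at=world.t))
                created.append(key)
    return created, ruptured


def adhesion_forces(
    world: World,
    assembly: Optional[Assembly] = None,
    viscous: bool = False,
    out_flat: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Flat per-interaction-node force array from all adhesion bonds, nN.

    Pairwise antisymmetric by construction; all-zero without bonds.
    """
    assembly = assembly or Assembly(world)
    f = out_flat if out_flat is not None else np.zeros_like(assembly.pos)
    keys, refs_a, refs_b, k, eta, L0 = world.bond_endpoint_arrays()
    if not keys:
        return f
    ia = assembly.flat_of(refs_a)
    ib = assembly.flat_of(refs_b)
    if viscous:
        va = _velocities(world, assembly)[ia]
        vb = _velocities(world, assembly)[ib]
        fa = pair_forces(assembly.pos[ia], assembly.pos[ib], va, vb, k, eta, L0)
    else:
        fa = elastic_pair_forces(assembly.pos[ia], assembly.pos[ib], k, L0)
    np.add.at(f, ia, fa)
    np.add.at(f, ib, -fa)
    return f


def _velocities(world: World, assembly: Assembly) -> np.ndarray:
    parts = []
    for cid in sorted(world.cells):
        parts.append(world.cells[cid].mem_vel)
    for eid in sorted(world.ecm_chains):
        parts.append(world.ecm_chains[eid].vel)
    return np.concatenate(parts, axis=0) if parts else np.zeros((0, 2))


def bond_eta_per_node(world: World, assembly: Assembly) -> np.ndarray:
    """Per-flat-node sum of bond dashpot viscosities (for drag lumping)."""
    s = np.zeros(len(assembly.pos))
    keys, refs_a, refs_b, _, eta, _ = world.bond_endpoint_arrays()
    if keys:
        np.add.at(s, assembly.flat_of(refs_a), eta)
        np.add.at(s, assembly.flat_of(refs_b), eta)
    return s


def repulsion_forces(
    world: World,
    rule: Optional[AdhesionRule] = None,
    assembly: Optional[Assembly] = None,
    out_flat: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Flat short-range elastic repulsion forces, momentum conserving.

    For each cell membrane node whose nearest distance d to a foreign
    membrane/ECM polyline is below ``d_rep``: magnitude k_rep*(d_rep - d)
    along the node's own inward membrane normal; the reaction acts on the
    nearest foreign segment's endpoints with barycentric weights.
    """
    rule = rule or world.adhesion_rule
    assembly = assembly or Assembly(world)
    f = out_flat if out_flat is not None else np.zeros_like(assembly.pos)
    if len(assembly.pos) == 0 or not world.cells:
        return f

    max_seg = _max_segment_length(world)
    pairs = assembly.tree.query_pairs(rule.d_rep + 0.5 * max_seg, output_type="ndarray")
    if len(pairs) == 0:
        return f
    oa = assembly.owner[pairs[:, 0]]
    ob = assembly.owner[pairs[:, 1]]
    pairs = pairs[oa != ob]
    if len(pairs) == 0:
        return f

    # candidate (node, foreign segment) pairs: both directions, both adjacent
    # segments of the counterpart node
    nodes = np.concatenate([pairs[:, 0], pairs[:, 1]])
    others = np.concatenate([pairs[:, 1], pairs[:, 0]])
    # only cell membrane nodes feel the primary force
    is_cell = assembly.ring[nodes] == RING_MEMBRANE
    nodes, others = nodes[is_cell], others[is_cell]
    if len(nodes) == 0:
        return f

    seg_a, seg_b, valid = _adjacent_segments(world, assembly, others)
    nodes = np.concatenate([nodes, nodes])[valid]
    sa = np.concatenate([seg_a[0], seg_b[0]])[valid]
    sb = np.concatenate([seg_a[1], seg_b[1]])[valid]
    if len(nodes) == 0:
        return f
    d, _, s = points_segments_distance(assembly.pos[nodes], assembly.pos[sa], assembly.pos[sb])
    in_range = d < rule.d_rep
    nodes, sa, sb, d, s = nodes[in_range], sa[in_range], sb[in_range], d[in_range], s[in_range]
    if len(nodes) == 0:
        return f

    # keep only each node's nearest foreign segment
    order = np.lexsort((d, nodes))
    nodes, sa, sb, d, s = nodes[order], sa[order], sb[order], d[order], s[order]
    first = np.ones(len(nodes), dtype=bool)
    first[1:] = nodes[1:] != nodes[:-1]
    nodes, sa, sb, d, s = nodes[first], sa[first], sb[first], d[first], s[first]

    mag = rule.k_rep * (rule.d_rep - d)
    normals = _membrane_normals_flat(world, assembly)
    direction = -normals[nodes]  # inward normal of the node's own membrane
    fn = mag[:, None] * direction
    np.add.at(f, nodes, fn)
    np.add.at(f, sa, -(1.0 - s)[:, None] * fn)
    np.add.at(f, sb, -s[:, None] * fn)
    return f


def _max_segment_length(world: World) -> float:
    m = 1.0
    for cell in world.cells.values():
        seg = np.linalg.norm(np.roll(cell.mem_pos, -1, axis=0) - cell.mem_pos, axis=1)
        m = max(m, float(seg.max()))
    for chain in world.ecm_chains.values():
        seg = np.linalg.norm(chain.segment_vectors(), axis=1)
        if len(seg):
            m = max(m, float(seg.max()))
    return m


def _adjacent_segments(world: World, assembly: Assembly, others: np.ndarray):
    """Flat endpoint indices of the two polyline segments adjacent to each
    counterpart node; open-chain ends yield one valid segment."""
    n_tot = len(others)
    prev_ok = np.ones(n_tot, dtype=bool)
    next_ok = np.ones(n_tot, dtype=bool)
    prev_idx = np.empty(n_tot, dtype=np.int64)
    next_idx = np.empty(n_tot, dtype=np.int64)
    owner = assembly.owner[others]
    idx = assembly.idx[others]
    starts = assembly.block_starts[np.searchsorted(assembly.block_ids, owner)]
    for oid in np.unique(owner):
        sel = owner == oid
        obj = assembly.world.owner_of(int(oid))
        n = obj.n
        closed = getattr(obj, "closed", True)  # cell membranes are closed rings
        i = idx[sel]
        if closed:
            prev_idx[sel] = (i - 1) % n
            next_idx[sel] = (i + 1) % n
        else:
            prev_idx[sel] = np.maximum(i - 1, 0)
            next_idx[sel] = np.minimum(i + 1, n - 1)
            prev_ok[sel] = i > 0
            next_ok[sel] = i < n - 1
    seg_prev = (starts + prev_idx, starts + idx)
    seg_next = (starts + idx, starts + next_idx)
    valid = np.concatenate([prev_ok, next_ok])
    return seg_prev, seg_next, valid


def _membrane_normals_flat(world: World, assembly: Assembly) -> np.ndarray:
    out = np.zeros_like(assembly.pos)
    for i, oid in enumerate(assembly.block_ids):
        cell = world.cells.get(int(oid))
        if cell is None:
            continue
        a = assembly.block_starts[i]
        out[a : a + cell.n] = outward_normals(cell.mem_pos)
    return out
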