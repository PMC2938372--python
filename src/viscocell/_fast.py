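"""Batched force/integration kernels used by the engine's main loop.

The per-module force operators (cell.py, adhesion.py, ecm.py) are the
readable reference implementations; stepping a populated world through them
costs thousands of small array operations per step.  This module flattens
every ring of every cell into one global node array per step and evaluates
each element category with a single vectorised pass.  The result is
numerically identical to the reference path (asserted in the test suite).

Flat layout: membrane blocks of all cells (ascending id), then ECM chains
(ascending id), then nucleus blocks.  The membrane+ECM prefix matches the
adhesion module's Assembly layout, so junction and repulsion forces can
accumulate straight into the same array.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .adhesion import Assembly
from .elements import RING_ECM, RING_MEMBRANE
from .processes import mitosis_forces
from .world import World


def fingerprint(world: World):
    """Cheap topology signature; cache is rebuilt when it changes."""
    return (
        tuple(
            (cid, c.n, c.chord is None)
            for cid, c in sorted(world.cells.items())
        ),
        tuple((eid, ch.n, ch.rigid) for eid, ch in sorted(world.ecm_chains.items())),
    )


class MechCache:
    """Static (per-topology) index arrays for the batched kernels."""

    def __init__(self, world: World) -> None:
        self.fp = fingerprint(world)
        self.cells = [world.cells[cid] for cid in sorted(world.cells)]
        self.ecms = [world.ecm_chains[eid] for eid in sorted(world.ecm_chains)]
        ns = np.array([c.n for c in self.cells], dtype=np.int64)
        es = np.array([ch.n for ch in self.ecms], dtype=np.int64)
        self.mem_starts = np.concatenate([[0], np.cumsum(ns)])[:-1] if len(ns) else np.zeros(0, np.int64)
        self.M = int(ns.sum())
        self.ecm_starts = self.M + (np.concatenate([[0], np.cumsum(es)])[:-1] if len(es) else np.zeros(0, np.int64))
        self.E = int(es.sum())
        self.nuc_starts = self.M + self.E + (np.concatenate([[0], np.cumsum(ns)])[:-1] if len(ns) else np.zeros(0, np.int64))
        self.N = self.M + self.E + int(ns.sum())

        def ring_indices(starts):
            idx, nxt, prv = [], [], []
            for s, c in zip(starts, self.cells):
                n = c.n
                ar = np.arange(n, dtype=np.int64)
                idx.append(s + ar)
                nxt.append(s + (ar + 1) % n)
                prv.append(s + (ar - 1) % n)
            cat = lambda parts: np.concatenate(parts) if parts else np.zeros(0, np.int64)
            return cat(idx), cat(nxt), cat(prv)

        self.mem_idx, self.mem_next, self.mem_prev = ring_indices(self.mem_starts)
        self.nuc_idx, self.nuc_next, self.nuc_prev = ring_indices(self.nuc_starts)

        def cat_f(parts):
            return np.concatenate(parts) if parts else np.zeros(0)

        self.mem_k = cat_f([c.mem_el.k for c in self.cells])
        self.nucmem_k = cat_f([c.nucmem_el.k for c in self.cells])
        self.radial_k = cat_f([c.radial.k for c in self.cells])

        chord_a, chord_b, chord_k = [], [], []
        for s, c in zip(self.nuc_starts, self.cells):
            if c.chord is not None:
                n = c.n
                ar = np.arange(n, dtype=np.int64)
                chord_a.append(s + ar)
                chord_b.append(s + (ar + n // 2) % n)
                chord_k.append(c.chord.k)
        self.chord_a = np.concatenate(chord_a) if chord_a else np.zeros(0, np.int64)
        self.chord_b = np.concatenate(chord_b) if chord_b else np.zeros(0, np.int64)
        self.chord_k = cat_f(chord_k)

        ecm_a, ecm_b, ecm_k = [], [], []
        for s, ch in zip(self.ecm_starts, self.ecms):
            ia, ib = ch.element_endpoints()
            ecm_a.append(s + ia)
            ecm_b.append(s + ib)
            ecm_k.append(ch.k)
        self.ecm_a = np.concatenate(ecm_a) if ecm_a else np.zeros(0, np.int64)
        self.ecm_b = np.concatenate(ecm_b) if ecm_b else np.zeros(0, np.int64)
        self.ecm_k = cat_f(ecm_k)

        # drag lumping: per-node incident dashpot sums
        mem_eta, nuc_eta = [], []
        for c in self.cells:
            me, ne = c.eta_sums()
            mem_eta.append(me)
            nuc_eta.append(ne)
        self.mem_eta = cat_f(mem_eta)
        self.nuc_eta = cat_f(nuc_eta)
        self.ecm_eta = cat_f([ch.eta_sums() for ch in self.ecms])
        self.ecm_drag = cat_f([ch.drag for ch in self.ecms])
        self.nuc_drag = cat_f([c.nuc_drag for c in self.cells])
        fixed = [np.full(ch.n, ch.rigid) for ch in self.ecms]
        self.ecm_fixed = np.concatenate(fixed) if fixed else np.zeros(0, bool)

        # Assembly prefix metadata (membrane + ECM blocks)
        owner = [np.full(c.n, c.id, np.int64) for c in self.cells] + [
            np.full(ch.n, ch.id, np.int64) for ch in self.ecms
        ]
        ring = [np.full(c.n, RING_MEMBRANE, np.int64) for c in self.cells] + [
            np.full(ch.n, RING_ECM, np.int64) for ch in self.ecms
        ]
        idx = [np.arange(c.n, dtype=np.int64) for c in self.cells] + [
            np.arange(ch.n, dtype=np.int64) for ch in self.ecms
        ]
        cat = lambda parts: np.concatenate(parts) if parts else np.zeros(0, np.int64)
        self.owner, self.ring, self.idx = cat(owner), cat(ring), cat(idx)
        self.block_ids = np.array(
            [c.id for c in self.cells] + [ch.id for ch in self.ecms], dtype=np.int64
        )
        self.block_starts = np.concatenate(
            [self.mem_starts, self.ecm_starts]
        ) if len(self.block_ids) else np.zeros(0, np.int64)

        self._bonds_version = None
        self._bond_arrays = None
        self._bond_eta = None

        # interaction-prefix polyline neighbours (for repulsion segments)
        pre_prev = [self.mem_prev]
        pre_next = [self.mem_next]
        prev_ok = [np.ones(self.M, bool)]
        next_ok = [np.ones(self.M, bool)]
        for s, ch in zip(self.ecm_starts, self.ecms):
            n = ch.n
            ar = np.arange(n, dtype=np.int64)
            if ch.closed:
                pre_prev.append(s + (ar - 1) % n)
                pre_next.append(s + (ar + 1) % n)
                prev_ok.append(np.ones(n, bool))
                next_ok.append(np.ones(n, bool))
            else:
                pre_prev.append(s + np.maximum(ar - 1, 0))
                pre_next.append(s + np.minimum(ar + 1, n - 1))
                prev_ok.append(ar > 0)
                next_ok.append(ar < n - 1)
        self.pre_prev = np.concatenate(pre_prev) if self.M + self.E else np.zeros(0, np.int64)
        self.pre_next = np.concatenate(pre_next) if self.M + self.E else np.zeros(0, np.int64)
        self.pre_prev_ok = np.concatenate(prev_ok) if self.M + self.E else np.zeros(0, bool)
        self.pre_next_ok = np.concatenate(next_ok) if self.M + self.E else np.zeros(0, bool)

    # ----------------------------------------------------------- per step
    def gather_positions(self) -> np.ndarray:
        pos = np.empty((self.N, 2))
        for s, c in zip(self.mem_starts, self.cells):
            pos[s : s + c.n] = c.mem_pos
        for s, ch in zip(self.ecm_starts, self.ecms):
            pos[s : s + ch.n] = ch.pos
        for s, c in zip(self.nuc_starts, self.cells):
            pos[s : s + c.n] = c.nuc_pos
        return pos

    def assembly(self, world: World, pos: np.ndarray) -> Assembly:
        return Assembly(
            world,
            _precomputed=(
                pos[: self.M + self.E],
                self.owner,
                self.ring,
                self.idx,
                self.block_ids,
                self.block_starts,
            ),
        )

    def bond_arrays(self, world: World, assembly: Assembly):
        if self._bonds_version != world._bonds_version:
            keys, refs_a, refs_b, k, eta, L0 = world.bond_endpoint_arrays()
            if keys:
                ia = assembly.flat_of(refs_a)
                ib = assembly.flat_of(refs_b)
            else:
                ia = ib = np.zeros(0, np.int64)
            self._bond_arrays = (ia, ib, k, L0)
            be = np.zeros(self.M + self.E)
            if len(ia):
                np.add.at(be, ia, eta)
                np.add.at(be, ib, eta)
            self._bond_eta = be
            self._bonds_version = world._bonds_version
        return self._bond_arrays, self._bond_eta


def _axial_spring(f, pos, a, b, k, L0):
    d = pos[b] - pos[a]
    L = np.sqrt(np.einsum("ij,ij->i", d, d))
    np.maximum(L, 1e-12, out=L)
    fa = (k * (L - L0) / L)[:, None] * d
    f[a] += fa
    f[b] -= fa


def membrane_normals(cache: MechCache, pos: np.ndarray) -> np.ndarray:
    """Outward unit normals of every membrane node (neighbour-chord rule)."""
    chord = pos[cache.mem_next] - pos[cache.mem_prev]
    cl = np.sqrt(np.einsum("ij,ij->i", chord, chord))
    np.maximum(cl, 1e-12, out=cl)
    out = np.empty((cache.M, 2))
    out[:, 0] = chord[:, 1] / cl
    out[:, 1] = -chord[:, 0] / cl
    return out


def fast_repulsion(world: World, cache: MechCache, pos: np.ndarray, f: np.ndarray,
                   rule, assembly, normals: np.ndarray) -> None:
    """Vectorised equivalent of adhesion.repulsion_forces (same contract)."""
    pre = cache.M + cache.E
    if pre == 0 or cache.M == 0:
        return
    seg = pos[cache.pre_next] - pos[:pre]
    seg_len = np.sqrt(np.einsum("ij,ij->i", seg, seg))
    max_seg = float(seg_len[cache.pre_next_ok].max()) if cache.pre_next_ok.any() else 1.0
    pairs = assembly.tree.query_pairs(rule.d_rep + 0.5 * max(1.0, max_seg), output_type="ndarray")
    if len(pairs) == 0:
        return
    keep = cache.owner[pairs[:, 0]] != cache.owner[pairs[:, 1]]
    pairs = pairs[keep]
    if len(pairs) == 0:
        return
    nodes = np.concatenate([pairs[:, 0], pairs[:, 1]])
    others = np.concatenate([pairs[:, 1], pairs[:, 0]])
    is_mem = cache.ring[nodes] == RING_MEMBRANE
    nodes, others = nodes[is_mem], others[is_mem]
    if len(nodes) == 0:
        return
    sa = np.concatenate([cache.pre_prev[others], others])
    sb = np.concatenate([others, cache.pre_next[others]])
    valid = np.concatenate([cache.pre_prev_ok[others], cache.pre_next_ok[others]])
    nodes2 = np.concatenate([nodes, nodes])[valid]
    sa, sb = sa[valid], sb[valid]
    ab = pos[sb] - pos[sa]
    denom = np.einsum("ij,ij->i", ab, ab)
    np.maximum(denom, 1e-24, out=denom)
    s = np.clip(np.einsum("ij,ij->i", pos[nodes2] - pos[sa], ab) / denom, 0.0, 1.0)
    c = pos[sa] + s[:, None] * ab
    dvec = pos[nodes2] - c
    d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    in_range = d < rule.d_rep
    if not in_range.any():
        return
    nodes2, sa, sb, d, s = (
        nodes2[in_range], sa[in_range], sb[in_range], d[in_range], s[in_range]
    )
    order = np.lexsort((d, nodes2))
    nodes2, sa, sb, d, s = nodes2[order], sa[order], sb[order], d[order], s[order]
    first = np.ones(len(nodes2), bool)
    first[1:] = nodes2[1:] != nodes2[:-1]
    nodes2, sa, sb, d, s = nodes2[first], sa[first], sb[first], d[first], s[first]
    mag = rule.k_rep * (rule.d_rep - d)
    fn = -mag[:, None] * normals[nodes2]
    for comp in (0, 1):
        f[:pre, comp] += np.bincount(nodes2, weights=fn[:, comp], minlength=pre)
        f[:pre, comp] -= np.bincount(sa, weights=(1.0 - s) * fn[:, comp], minlength=pre)
        f[:pre, comp] -= np.bincount(sb, weights=s * fn[:, comp], minlength=pre)


def compute_forces(world: World, cache: MechCache, pos: np.ndarray, cfg, assembly) -> np.ndarray:
    f = np.zeros((cache.N, 2))
    cells = cache.cells
    if cells:
        mem_L0 = np.concatenate([c.mem_el.L0 for c in cells])
        nucmem_L0 = np.concatenate([c.nucmem_el.L0 for c in cells])
        radial_L0 = np.concatenate([c.radial.L0 for c in cells])
        _axial_spring(f, pos, cache.mem_idx, cache.mem_next, cache.mem_k, mem_L0)
        _axial_spring(f, pos, cache.nuc_idx, cache.nuc_next, cache.nucmem_k, nucmem_L0)
        _axial_spring(f, pos, cache.mem_idx, cache.nuc_idx, cache.radial_k, radial_L0)
        if len(cache.chord_a):
            chord_L0 = np.concatenate(
                [c.chord.L0 for c in cells if c.chord is not None]
            )
            _axial_spring(f, pos, cache.chord_a, cache.chord_b, cache.chord_k, chord_L0)
        if cfg.pressure:
            chord = pos[cache.mem_next] - pos[cache.mem_prev]
            dp = np.repeat(
                [c.P_in - world.p_env for c in cells], [c.n for c in cells]
            )
            f[: cache.M, 0] += 0.5 * dp * chord[:, 1]
            f[: cache.M, 1] -= 0.5 * dp * chord[:, 0]
        if cfg.mitosis:
            for s_m, s_n, c in zip(cache.mem_starts, cache.nuc_starts, cells):
                if c.state == "mitotic" and c.mitosis is not None:
                    fm, fn = mitosis_forces(c)
                    f[s_m : s_m + c.n] += fm
                    f[s_n : s_n + c.n] += fn
        if cfg.external and world.external_force is not None:
            f[: cache.M] += world.external_force(pos[: cache.M])
    if len(cache.ecm_a):
        ecm_L0 = np.concatenate([ch.L0 for ch in cache.ecms if ch.n_elements])
        _axial_spring(f, pos, cache.ecm_a, cache.ecm_b, cache.ecm_k, ecm_L0)
    if cfg.adhesion and world.bonds:
        (ia, ib, k, L0), _ = cache.bond_arrays(world, assembly)
        if len(ia):
            d = pos[ib] - pos[ia]
            L = np.sqrt(np.einsum("ij,ij->i", d, d))
            np.maximum(L, 1e-12, out=L)
            fa = (k * (L - L0) / L)[:, None] * d
            pre = cache.M + cache.E
            for comp in (0, 1):
                f[:pre, comp] += np.bincount(ia, weights=fa[:, comp], minlength=pre)
                f[:pre, comp] -= np.bincount(ib, weights=fa[:, comp], minlength=pre)
    if cfg.repulsion and (world.cells and (len(world.cells) > 1 or world.ecm_chains)):
        normals = membrane_normals(cache, pos)
        fast_repulsion(world, cache, pos, f, world.adhesion_rule, assembly, normals)
    return f


def integrate(world: World, cache: MechCache, pos: np.ndarray, f: np.ndarray,
              dt: float, assembly, substrate) -> float:
    _, bond_eta = cache.bond_arrays(world, assembly)
    # effective drag: base + incident dashpot viscosities (+ bond dashpots)
    if substrate is not None:
        mem_drag = substrate(pos[: cache.M])
        for s, c in zip(cache.mem_starts, cache.cells):
            if c.motile:
                mem_drag[s : s + c.n] = c.mem_drag
    else:
        mem_drag = (
            np.concatenate([c.mem_drag for c in cache.cells])
            if cache.cells
            else np.zeros(0)
        )
    d = np.empty(cache.N)
    d[: cache.M] = mem_drag + cache.mem_eta
    d[cache.M : cache.M + cache.E] = cache.ecm_drag + cache.ecm_eta
    d[cache.M + cache.E :] = cache.nuc_drag + cache.nuc_eta
    d[: cache.M + cache.E] += bond_eta
    if np.any(d <= 0):
        raise ValueError("non-positive effective drag")
    v = f / d[:, None]
    if cache.E and cache.ecm_fixed.any():
        v[cache.M : cache.M + cache.E][cache.ecm_fixed] = 0.0
    pos += v * dt
    for s, c in zip(cache.mem_starts, cache.cells):
        c.mem_pos[:] = pos[s : s + c.n]
        c.mem_vel[:] = v[s : s + c.n]
    for s, ch in zip(cache.ecm_starts, cache.ecms):
        if not ch.rigid:
            ch.pos[:] = pos[s : s + ch.n]
        ch.vel[:] = v[s : s + ch.n]
    for s, c in zip(cache.nuc_starts, cache.cells):
        c.nuc_pos[:] = pos[s : s + c.n]
        c.nuc_vel[:] = v[s : s + c.n]
    world.t += dt
    return float(np.max(np.abs(v))) * dt if cache.N else 0.0
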