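"""World container: cells, ECM chains, adhesion bonds, environment, clock, RNG."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .cell import Cell
from .config import AdhesionRule, WorldConfig
from .ecm import ECMChain, SubstrateField
from .elements import RING_ECM, RING_MEMBRANE, NodeRef


@dataclass
class Bond:
    """One adherens-junction Voigt subunit between nodes of different owners."""

    k: float
    eta: float
    L0: float
    created_at: float = 0.0


BondKey = Tuple[NodeRef, NodeRef]


def bond_key(ref_a: NodeRef, ref_b: NodeRef) -> BondKey:
    return (ref_a, ref_b) if ref_a <= ref_b else (ref_b, ref_a)


class World:
    """All simulation state: agents, junctions, environment, clock, RNG."""

    def __init__(
        self,
        *,
        p_env: float = 0.0,
        adhesion_rule: Optional[AdhesionRule] = None,
        substrate: Optional[SubstrateField] = None,
        external_force: Optional[Callable[[np.ndarray], np.ndarray]] = None,
        seed: int = 0,
    ) -> None:
        self.cells: Dict[int, Cell] = {}
        self.ecm_chains: Dict[int, ECMChain] = {}
        self.bonds: Dict[BondKey, Bond] = {}
        self.p_env = float(p_env)
        self.adhesion_rule = adhesion_rule or AdhesionRule()
        self.substrate = substrate
        self.external_force = external_force
        self.t = 0.0
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.config = WorldConfig(p_env=p_env, adhesion=self.adhesion_rule)
        self._bonds_version = 0
        self._bond_arrays = None
        self._next_cid = 0

    def new_cell_id(self) -> int:
        cid = self._next_cid
        self._next_cid += 1
        return cid

    # ------------------------------------------------------------- membership
    def add_cell(self, cell: Cell) -> Cell:
        if cell.id in self.cells or cell.id in self.ecm_chains:
            raise ValueError(f"duplicate owner id {cell.id}")
        self.cells[cell.id] = cell
        self._next_cid = max(self._next_cid, cell.id + 1)
        return cell

    def add_ecm(self, chain: ECMChain) -> ECMChain:
        if chain.id in self.cells or chain.id in self.ecm_chains:
            raise ValueError(f"duplicate owner id {chain.id}")
        self.ecm_chains[chain.id] = chain
        return chain

    def remove_cell(self, cid: int) -> None:
        self.cells.pop(cid)
        self.drop_bonds_of(cid)

    # ------------------------------------------------------------------ bonds
    def _touch_bonds(self) -> None:
        self._bonds_version += 1
        self._bond_arrays = None

    def add_bond(self, ref_a: NodeRef, ref_b: NodeRef, bond: Bond) -> None:
        if ref_a[0] == ref_b[0]:
            raise ValueError("adhesion bonds must join different owners")
        self.bonds[bond_key(ref_a, ref_b)] = bond
        self._touch_bonds()

    def remove_bonds(self, keys) -> None:
        for key in keys:
            self.bonds.pop(key, None)
        if keys:
            self._touch_bonds()

    def drop_bonds_of(self, owner: int) -> None:
        dead = [k for k in self.bonds if k[0][0] == owner or k[1][0] == owner]
        self.remove_bonds(dead)

    def remap_bonds_after_insert(
        self, owner: int, inserted_after: int, ring_code: int = RING_MEMBRANE
    ) -> None:
        """Shift bond node indices after an insertion at position
        ``inserted_after``+1 on ``owner``'s ring ``ring_code``."""
        changed = {}
        dead = []
        for key, bond in self.bonds.items():
            new_key = key
            for side in (0, 1):
                o, ring, idx = key[side]
                if o == owner and ring == ring_code and idx > inserted_after:
                    ref = (o, ring, idx + 1)
                    new_key = (ref, new_key[1]) if side == 0 else (new_key[0], ref)
            if new_key != key:
                dead.append(key)
                changed[bond_key(*new_key)] = bond
        if dead:
            for k in dead:
                self.bonds.pop(k)
            self.bonds.update(changed)
            self._touch_bonds()

    # ------------------------------------------------------------ node lookup
    def owner_of(self, oid: int):
        return self.cells.get(oid) or self.ecm_chains.get(oid)

    def pos_of(self, ref: NodeRef) -> np.ndarray:
        oid, ring, idx = ref
        if ring == RING_ECM:
            return self.ecm_chains[oid].pos[idx]
        cell = self.cells[oid]
        return cell.mem_pos[idx] if ring == RING_MEMBRANE else cell.nuc_pos[idx]

    def bond_endpoint_arrays(self):
        """Cached (refs_a, refs_b) index triplet arrays of the bond set, in
        deterministic (sorted-key) order."""
        if self._bond_arrays is None:
            keys = sorted(self.bonds.keys())
            if keys:
                a = np.array([k[0] for k in keys], dtype=np.int64)
                b = np.array([k[1] for k in keys], dtype=np.int64)
                k_arr = np.array([self.bonds[k].k for k in keys])
                eta = np.array([self.bonds[k].eta for k in keys])
                L0 = np.array([self.bonds[k].L0 for k in keys])
            else:
                a = b = np.zeros((0, 3), dtype=np.int64)
                k_arr = eta = L0 = np.zeros(0)
            self._bond_arrays = (keys, a, b, k_arr, eta, L0)
        return self._bond_arrays

    # ------------------------------------------------------- interaction flat
    def interaction_nodes(self):
        """Flat arrays over all adhesion/repulsion-eligible nodes (cell
        membranes and ECM chains): positions, owner ids, ring codes, indices.
        """
        pos_parts, owner_parts, ring_parts, idx_parts = [], [], [], []
        for cid in sorted(self.cells):
            cell = self.cells[cid]
            pos_parts.append(cell.mem_pos)
            owner_parts.append(np.full(cell.n, cid, dtype=np.int64))
            ring_parts.append(np.full(cell.n, RING_MEMBRANE, dtype=np.int64))
            idx_parts.append(np.arange(cell.n, dtype=np.int64))
        for eid in sorted(self.ecm_chains):
            chain = self.ecm_chains[eid]
            pos_parts.append(chain.pos)
            owner_parts.append(np.full(chain.n, eid, dtype=np.int64))
            ring_parts.append(np.full(chain.n, RING_ECM, dtype=np.int64))
            idx_parts.append(np.arange(chain.n, dtype=np.int64))
        if not pos_parts:
            z = np.zeros((0,), dtype=np.int64)
            return np.zeros((0, 2)), z, z, z
        return (
            np.concatenate(pos_parts, axis=0),
            np.concatenate(owner_parts),
            np.concatenate(ring_parts),
            np.concatenate(idx_parts),
        )

    def validate(self) -> None:
        for key in self.bonds:
            for ref in key:
                oid, ring, idx = ref
                owner = self.owner_of(oid)
                if owner is None:
                    raise ValueError(f"bond endpoint {ref} has no owner")
                n = owner.n
                if idx >= n:
                    raise ValueError(f"bond endpoint index {ref} out of range")
            if key[0][0] == key[1][0]:
                raise ValueError("bond joins nodes of the same owner")
        for cell in self.cells.values():
            cell.validate(check_nucleus_inside=False)
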