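import numpy as np
import pytest

from viscocell import Cell, CellParams, EcmParams, World
from viscocell.adhesion import (
    Assembly,
    adhesion_forces,
    repulsion_forces,
    update_adhesions,
)
from viscocell.config import AdhesionRule
from viscocell.ecm import ECMChain
from viscocell.engine import EngineConfig, run
from viscocell.processes import start_apoptosis
from viscocell.world import bond_key


def cell_and_probe(d0: float, params=None):
    """A cell plus a single movable ECM probe node at distance d0 from
    membrane node 0 (along its outward radius)."""
    params = params or CellParams(n_points=20)
    w = World(seed=0)
    c = Cell.build(params, cid=0)
    w.add_cell(c)
    u = c.mem_pos[0] / np.linalg.norm(c.mem_pos[0])
    probe = ECMChain(
        (c.mem_pos[0] + d0 * u)[None, :], EcmParams(), closed=False, rigid=False
    )
    w.add_ecm(probe)
    return w, c, probe, u


def set_probe_distance(c, probe, u, d):
    probe.pos[0] = c.mem_pos[0] + d * u


class TestBondLifecycle:
    def test_creation_below_da(self, rule):
        w, c, probe, u = cell_and_probe(0.5 * rule.d_a)
        created, _ = update_adhesions(w, rule)
        assert len(created) == 1
        assert len(w.bonds) == 1

    def test_no_same_owner_bonds(self, rule, params20):
        w = World(seed=0)
        w.add_cell(Cell.build(params20, cid=0))  # plenty of self-proximity
        update_adhesions(w, rule)
        assert len(w.bonds) == 0

    def test_hysteresis_cycle(self, rule):
        """d_a-eps -> (d_a+d_r)/2 -> d_a-eps never ruptures; > d_r always."""
        eps = 0.05
        w, c, probe, u = cell_and_probe(rule.d_a - eps)
        update_adhesions(w, rule)
        (key,) = list(w.bonds)
        bond = w.bonds[key]
        for d in (0.5 * (rule.d_a + rule.d_r), rule.d_a - eps,
                  0.5 * (rule.d_a + rule.d_r), rule.d_a - eps):
            set_probe_distance(c, probe, u, d)
            update_adhesions(w, rule)
            assert w.bonds.get(key) is bond  # same junction object persists
        set_probe_distance(c, probe, u, 1.01 * rule.d_r)
        _, ruptured = update_adhesions(w, rule)
        assert key in ruptured and key not in w.bonds

    @pytest.mark.parametrize("eps_frac", [0.01, 0.1, 0.5])
    def test_hysteresis_band_exhaustive(self, rule, eps_frac):
        eps = eps_frac * rule.d_a
        w, c, probe, u = cell_and_probe(rule.d_a - eps)
        update_adhesions(w, rule)
        assert len(w.bonds) == 1
        set_probe_distance(c, probe, u, rule.d_r - 1e-6)
        update_adhesions(w, rule)
        assert len(w.bonds) == 1   # inside the band: persists
        set_probe_distance(c, probe, u, rule.d_r + 1e-6)
        update_adhesions(w, rule)
        assert len(w.bonds) == 0   # crossing d_r always ruptures

    def test_apoptotic_cell_disconnects_unilaterally(self, rule):
        w, c, probe, u = cell_and_probe(0.5 * rule.d_a)
        update_adhesions(w, rule)
        assert len(w.bonds) == 1
        start_apoptosis(c, w)
        assert len(w.bonds) == 0
        update_adhesions(w, rule)  # and no re-adhesion while apoptotic
        assert len(w.bonds) == 0

    def test_bond_parameters_are_series_combination(self, rule):
        w, c, probe, u = cell_and_probe(0.5 * rule.d_a)
        update_adhesions(w, rule)
        bond = next(iter(w.bonds.values()))
        ka, kb = c.params.k_adhesion, probe.params.k_adhesion
        assert bond.k == pytest.approx(ka * kb / (ka + kb))


class TestAdhesionForces:
    def test_no_bonds_zero(self, two_touching_cells):
        f = adhesion_forces(two_touching_cells)
        assert np.all(f == 0)

    def test_stretched_bond_attracts(self, rule):
        w, c, probe, u = cell_and_probe(0.5 * rule.d_a)
        update_adhesions(w, rule)
        bond = next(iter(w.bonds.values()))
        set_probe_distance(c, probe, u, bond.L0 + 1.0)
        asm = Assembly(w)
        f = adhesion_forces(w, asm)
        # membrane node 0 pulled outward toward the probe, probe pulled back
        i_mem = 0
        i_probe = len(asm.pos) - 1
        assert f[i_mem] @ u > 0
        assert np.allclose(f[i_probe], -f[i_mem])

    def test_world_momentum_zero(self, two_touching_cells):
        w = two_touching_cells
        run(w, EngineConfig(dt=0.01, n_steps=50, biology=False))
        f = adhesion_forces(w)
        assert len(w.bonds) > 0
        assert np.linalg.norm(f.sum(axis=0)) < 1e-9 * max(np.abs(f).sum(), 1e-12)


class TestRepulsion:
    def test_zero_beyond_range(self, params20, rule):
        w = World(seed=0)
        w.add_cell(Cell.build(params20, center=(-20, 0), cid=0))
        w.add_cell(Cell.build(params20, center=(20, 0), cid=1))
        f = repulsion_forces(w, rule)
        assert np.all(f == 0)

    def test_linear_law_magnitude(self, rule):
        """A membrane node at d = d_rep/2 from a flat foreign surface feels
        exactly k_rep*(d_rep - d) along its inward normal."""
        d = rule.d_rep / 2
        p = CellParams(n_points=20)
        w = World(seed=0)
        cell = Cell.build(p, cid=0)
        w.add_cell(cell)
        bottom = int(np.argmin(cell.mem_pos[:, 1]))
        y = cell.mem_pos[bottom, 1] - d
        seg = ECMChain(
            np.array([[-2.0, y], [2.0, y]]), EcmParams(), closed=False, rigid=True
        )
        w.add_ecm(seg)
        f = repulsion_forces(w, rule)
        mag = np.linalg.norm(f[bottom])
        assert mag == pytest.approx(rule.k_rep * (rule.d_rep - d), rel=1e-6)
        assert f[bottom][1] > 0  # pushed back along the inward normal

    def test_momentum_conserved(self, params20, rule):
        w = World(seed=0)
        w.add_cell(Cell.build(params20, center=(-7.0, 0), cid=0))
        w.add_cell(Cell.build(params20, center=(7.5, 0.4), cid=1))  # overlapping
        f = repulsion_forces(w, rule)
        assert np.abs(f).sum() > 0
        assert np.linalg.norm(f.sum(axis=0)) < 1e-9 * np.abs(f).sum()

    def test_overlapping_cells_separate(self, params20):
        w = World(seed=0)
        a = Cell.build(params20, center=(-6.0, 0), cid=0)
        b = Cell.build(params20, center=(6.0, 0), cid=1)  # 3 um overlap
        w.add_cell(a)
        w.add_cell(b)
        run(w, EngineConfig(dt=0.01, n_steps=4000, biology=False, adhesion=False))
        inter = a.membrane_polygon().intersection(b.membrane_polygon()).area
        assert inter < 0.01 * a.area()

    def test_fast_repulsion_matches_reference(self, params20, rule):
        from viscocell import _fast

        w = World(seed=0)
        w.add_cell(Cell.build(params20, center=(-7.0, 0), cid=0))
        w.add_cell(Cell.build(params20, center=(7.5, 0.4), cid=1))
        ref = repulsion_forces(w, rule)
        cache = _fast.MechCache(w)
        pos = cache.gather_positions()
        asm = cache.assembly(w, pos)
        fast = np.zeros((cache.N, 2))
        _fast.fast_repulsion(
            w, cache, pos, fast, rule, asm, _fast.membrane_normals(cache, pos)
        )
        assert np.allclose(fast[: cache.M + cache.E], ref, atol=1e-12)
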