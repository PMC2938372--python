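import numpy as np
import pytest

from viscocell import Cell, CellParams, EcmParams, World
from viscocell.adhesion import Assembly, update_adhesions
from viscocell.ecm import ECMChain
from viscocell.elements import RING_ECM, RING_MEMBRANE, RING_NUCLEUS
from viscocell.engine import (
    EngineConfig,
    SimulationUnstable,
    accumulate_forces,
    integrate_step,
    run,
    spring_potential,
    stability_bound,
    world_force_total,
)
from viscocell.scenarios import ScenarioSpec, make_world


def single_free_node_world(drag: float) -> World:
    """One unconnected ECM node: the simplest moving body."""
    w = World(seed=0)
    chain = ECMChain(
        np.array([[0.0, 0.0]]), EcmParams(), closed=False, rigid=False,
        drag_profile=np.array([drag]),
    )
    w.add_ecm(chain)
    return w


class TestIntegrator:
    def test_constant_force_exact_displacement(self):
        D, F, dt = 2.5, np.array([3.0, -1.0]), 0.05
        w = single_free_node_world(D)
        chain = next(iter(w.ecm_chains.values()))
        forces = accumulate_forces(w)
        forces[(chain.id, RING_ECM)][0] = F
        integrate_step(w, dt, forces)
        assert np.array_equal(chain.pos[0], (F / D) * dt)  # exact, not approx

    def test_zero_force_only_time_advances(self):
        w = single_free_node_world(1.0)
        chain = next(iter(w.ecm_chains.values()))
        integrate_step(w, 0.1)
        assert np.all(chain.pos == 0.0)
        assert w.t == pytest.approx(0.1)

    def test_voigt_relaxation_matches_closed_form(self):
        """Free end of a stretched Voigt element decays as
        x0 * exp(-k t / (D + eta))."""
        k, eta, D, L0, x0 = 2.0, 0.5, 1.0, 3.0, 1.2
        dt = 0.009 * (D + eta) / k  # below the 1%-accuracy bound
        params = EcmParams(k=k, eta=eta)
        chain = ECMChain(
            np.array([[0.0, 0.0], [L0 + x0, 0.0]]),
            params,
            closed=False,
            rigid=False,
            drag_profile=np.array([1e14, D]),  # near wall-anchored first node
        )
        chain.L0[:] = L0
        w = World(seed=0)
        w.add_ecm(chain)
        sim, ana = [], []
        for step in range(1500):
            integrate_step(w, dt)
            sim.append(chain.pos[1, 0] - L0)
            ana.append(x0 * np.exp(-k * w.t / (D + eta)))
        sim, ana = np.array(sim), np.array(ana)
        rms = np.sqrt(np.mean((sim - ana) ** 2)) / x0
        assert rms < 0.01

    def test_zero_drag_rejected(self):
        w = single_free_node_world(0.0)
        with pytest.raises(ValueError):
            integrate_step(w, 0.01)


class TestStability:
    def test_dt_above_bound_rejected(self, params40):
        w = World(seed=0)
        w.add_cell(Cell.build(params40, cid=0))
        bound = stability_bound(w)
        with pytest.raises(ValueError):
            run(w, EngineConfig(dt=bound * 1.01, n_steps=10))

    def test_energy_nonincreasing_at_half_bound(self, params40):
        w = World(seed=0)
        c = Cell.build(params40, cid=0)
        c.P_in = 0.0
        c.mem_pos *= 1.1  # perturbed: free relaxation back to rest
        w.add_cell(c)
        dt = 0.5 * stability_bound(w)
        cfg = EngineConfig(dt=dt, n_steps=1, biology=False)
        e_prev = spring_potential(w)
        for _ in range(300):
            run(w, cfg)
            e = spring_potential(w)
            assert e <= e_prev + 1e-12
            e_prev = e

    def test_instability_abort(self, params40):
        w = World(seed=0)
        c = Cell.build(params40, cid=0)
        c.P_in = 1e7  # absurd turgor: blow-up detected, not silently wrong
        w.add_cell(c)
        cfg = EngineConfig(dt=0.01, n_steps=50, biology=False, check_stability=False)
        with pytest.raises(SimulationUnstable):
            run(w, cfg)


class TestConservation:
    def test_two_bonded_cells_world_force_balance(self, two_touching_cells):
        w = two_touching_cells
        cfg = EngineConfig(dt=0.01, biology=False)
        for _ in range(200):
            update_adhesions(w)
            forces = accumulate_forces(w, cfg)
            total = world_force_total(forces)
            scale = sum(np.abs(f).sum() for f in forces.values())
            assert np.linalg.norm(total) <= 1e-9 * max(scale, 1e-12)
            integrate_step(w, cfg.dt, forces, cfg)
        assert len(w.bonds) > 0  # the system actually adhered

    def test_drag_weighted_centroid_drift(self, two_touching_cells):
        """No external field: the drag-weighted centroid is invariant."""
        w = two_touching_cells

        def weighted_centroid():
            num = np.zeros(2)
            den = 0.0
            for c in w.cells.values():
                me, ne = c.eta_sums()
                dm = c.mem_drag + me
                dn = c.nuc_drag + ne
                num += (dm[:, None] * c.mem_pos).sum(0) + (dn[:, None] * c.nuc_pos).sum(0)
                den += dm.sum() + dn.sum()
            return num / den

        run(w, EngineConfig(dt=0.01, n_steps=50, biology=False))  # settle bonds
        start = weighted_centroid()
        run(w, EngineConfig(dt=0.01, n_steps=1000, biology=False, adhesion=False))
        assert np.linalg.norm(weighted_centroid() - start) < 1e-6


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        logs = []
        finals = []
        for _ in range(2):
            w, cfg = make_world(ScenarioSpec("monolayer", {"drag": 5e-4}, seed=7))
            cfg.n_steps = 400
            res = run(w, cfg)
            logs.append([e.as_tuple() for e in res.events])
            finals.append(
                np.concatenate([w.cells[c].mem_pos.ravel() for c in sorted(w.cells)])
            )
        assert logs[0] == logs[1]
        assert np.array_equal(finals[0], finals[1])

    def test_different_seeds_diverge(self):
        logs = []
        for seed in (1, 2):
            w, cfg = make_world(ScenarioSpec("monolayer", {"drag": 5e-4}, seed=seed))
            cfg.n_steps = 1500
            res = run(w, cfg)
            logs.append([e.as_tuple() for e in res.events])
        assert logs[0] != logs[1]


class TestFastPathEquivalence:
    def test_flat_kernels_match_reference_operators(self, params20):
        from viscocell import _fast
        from viscocell.ecm import build_ecm

        w = World(seed=3)
        for i, cx in enumerate((-16.0, 0.0, 16.0)):
            w.add_cell(Cell.build(params20, center=(cx, 8.2), cid=i))
        w.add_ecm(build_ecm("line", EcmParams(), length=60.0))
        run(w, EngineConfig(dt=0.01, n_steps=100))  # entangle: bonds + contacts
        cache = _fast.MechCache(w)
        pos = cache.gather_positions()
        asm = cache.assembly(w, pos)
        cfg = EngineConfig()
        fast = _fast.compute_forces(w, cache, pos, cfg, asm)
        ref = accumulate_forces(w, cfg)
        for s, c in zip(cache.mem_starts, cache.cells):
            assert np.allclose(fast[s : s + c.n], ref[(c.id, RING_MEMBRANE)], atol=1e-12)
        for s, c in zip(cache.nuc_starts, cache.cells):
            assert np.allclose(fast[s : s + c.n], ref[(c.id, RING_NUCLEUS)], atol=1e-12)
        for s, ch in zip(cache.ecm_starts, cache.ecms):
            assert np.allclose(fast[s : s + ch.n], ref[(ch.id, RING_ECM)], atol=1e-12)
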