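import numpy as np
import pytest

from viscocell import Cell, CellParams, World
from viscocell.cell import StructuralError
from viscocell.elements import LABEL_CODES
from viscocell.engine import EngineConfig, run
from viscocell.processes import (
    MitosisState,
    add_growth_point,
    apoptosis_step,
    division_target_points,
    ecm_contact_map,
    effective_growth_region,
    enable_motility,
    growth_state,
    mitosis_forces,
    motility_update,
    nuclear_separation,
    partition_cell,
    polarize,
    reap,
    select_division_axis,
    split_cell,
    start_apoptosis,
)


class TestGrowthGating:
    def test_stop_region(self, cell40):
        cell40.V_rest = cell40.area() / 0.8  # V_cur = 0.8 V_rest <= c_s
        assert growth_state(cell40) == "stop"

    def test_growth_region(self, cell40):
        cell40.V_rest = cell40.area()  # V_cur = V_rest >= c_g
        assert growth_state(cell40) == "growth"

    def test_intermediate_retains_previous(self, cell40):
        cell40.V_rest = cell40.area()
        assert effective_growth_region(cell40) == "growth"
        cell40.V_rest = cell40.area() / 0.925  # between c_s and c_g
        assert growth_state(cell40) == "intermediate"
        assert effective_growth_region(cell40) == "growth"  # hysteresis memory
        cell40.V_rest = cell40.area() / 0.8
        assert effective_growth_region(cell40) == "stop"
        cell40.V_rest = cell40.area() / 0.925
        assert effective_growth_region(cell40) == "stop"

    def test_growth_never_fires_in_stop_region(self, params20):
        w = World(seed=0)
        c = Cell.build(params20, cid=0)
        c.V_rest = c.area() / 0.5  # deeply compressed
        w.add_cell(c)
        res = run(w, EngineConfig(dt=0.01, n_steps=500))
        assert not any(e.kind == "growth" for e in res.events)


class TestGrowthEvents:
    def test_doubling_targets(self):
        # smallest even ring size whose squared ratio doubles the area
        assert division_target_points(40) == 58
        assert division_target_points(20) == 30

    def test_add_growth_point_counts(self, cell40, rng):
        add_growth_point(cell40, rng)
        assert cell40.n == 41
        assert cell40.state == "growing"

    def test_blocked_during_mitosis(self, cell40, rng):
        partition_cell(cell40, select_division_axis(cell40))
        with pytest.raises(StructuralError):
            add_growth_point(cell40, rng)

    def test_rest_volume_doubles_at_target(self, cell40, rng):
        v0 = cell40.V_rest
        target = division_target_points(cell40.n0)
        while cell40.n < target:
            add_growth_point(cell40, rng)
        assert cell40.n == 58
        assert cell40.V_rest >= 2 * v0


class TestDivisionAxis:
    def test_perpendicular_to_elongation(self, cell40):
        cell40.mem_pos[:, 0] *= 1.5  # elongate along x
        cell40.nuc_pos[:, 0] *= 1.5
        axis = select_division_axis(cell40)
        assert abs(axis.direction @ np.array([0.0, 1.0])) > 0.99

    def test_degenerate_tie_break_through_node0(self, cell40):
        axis = select_division_axis(cell40)  # perfect regular ring
        expect = cell40.mem_pos[0] - cell40.nucleus_centroid()
        expect /= np.linalg.norm(expect)
        assert abs(axis.direction @ expect) > 0.999999

    def test_polarized_axis_perpendicular_to_basal_stretch(self, cell40):
        bottom = cell40.mem_pos[:, 1] < -0.8 * cell40.params.radius
        polarize(cell40, bottom)
        axis = select_division_axis(cell40)
        # basal stretch is horizontal, so the axis is vertical
        assert abs(axis.direction @ np.array([0.0, 1.0])) > 0.99


class TestPartitionAndForces:
    def test_group_sizes_and_chords(self, cell40):
        st = partition_cell(cell40, select_division_axis(cell40))
        na = int(st.group_a.sum())
        nb = cell40.n - na
        assert abs(na - nb) <= 1
        assert cell40.chord is None  # nuclear subunits eliminated
        assert cell40.state == "mitotic"

    def test_anchor_is_nearest_node_to_axis(self, cell40):
        from viscocell.processes import DivisionAxis

        anchor = cell40.nucleus_centroid()
        d = cell40.mem_pos[13] - anchor
        axis = DivisionAxis(anchor, d / np.linalg.norm(d))
        st = partition_cell(cell40, axis)
        assert st.anchor_index == 13

    def test_forces_sum_to_zero(self, cell40):
        partition_cell(cell40, select_division_axis(cell40))
        f_mem, f_nuc = mitosis_forces(cell40)
        total = f_mem.sum(axis=0) + f_nuc.sum(axis=0)
        assert np.linalg.norm(total) < 1e-9 * (np.abs(f_mem).sum() + np.abs(f_nuc).sum())

    def test_separation_increases_under_pulling(self, cell40):
        st = partition_cell(cell40, select_division_axis(cell40))
        sep0 = nuclear_separation(cell40)
        for _ in range(100):
            _, f_nuc = mitosis_forces(cell40)
            cell40.nuc_pos += 0.01 * f_nuc / cell40.nuc_drag[:, None]
            sep = nuclear_separation(cell40)
            assert sep > sep0
            sep0 = sep


class TestSplit:
    @pytest.fixture
    def divided(self):
        """Run a 40-point cell through growth and its first division."""
        import viscocell as vc

        parent_area = {}

        def watch(world, events):
            for c in world.cells.values():
                if c.state == "mitotic":
                    parent_area["v"] = c.area()

        w, cfg = vc.make_world(
            vc.ScenarioSpec("single_cell", {"grow": 1, "divide": 1}, seed=3)
        )
        cfg.n_steps = 200000
        cfg.hooks = [watch]
        cfg.stop_when = lambda ww: len(ww.cells) >= 2
        res = run(w, cfg)
        assert any(e.kind == "division" for e in res.events)
        return w, parent_area["v"]

    def test_daughter_bookkeeping(self, divided):
        w, parent_area = divided
        cells = list(w.cells.values())
        assert len(cells) == 2
        for d in cells:
            assert d.n == 40
            assert len(d.nuc_pos) == 40
            d.validate(check_nucleus_inside=False)
            for el in (d.mem_el, d.nucmem_el, d.radial, d.chord):
                assert len(el.k) == 40

    def test_daughter_area_balance(self, divided):
        w, parent_area = divided
        a = sorted(c.area() for c in w.cells.values())
        assert a[1] / a[0] < 1.10
        assert sum(a) == pytest.approx(parent_area, rel=0.05)

    def test_node_count_conserved_at_surgery(self, cell40):
        st = partition_cell(cell40, select_division_axis(cell40))
        assert len(st.order_a) + len(st.order_b) == cell40.n


class TestApoptosis:
    def test_start_shrinks_rest_lengths_fivefold(self, cell40):
        L0 = cell40.mem_el.L0.copy()
        start_apoptosis(cell40, p_env=0.0)
        assert np.allclose(cell40.mem_el.L0, L0 / 5)
        assert cell40.P_in == 0.0
        assert cell40.state == "apoptotic"

    def test_idempotent(self, cell40):
        start_apoptosis(cell40)
        L0 = cell40.mem_el.L0.copy()
        start_apoptosis(cell40)  # double start: no-op
        assert np.array_equal(cell40.mem_el.L0, L0)

    def test_area_decreases_until_reaped(self, params20):
        w = World(seed=0)
        c = Cell.build(params20, cid=0)
        w.add_cell(c)
        start_apoptosis(c, w)
        apoptosis_step(c)
        areas = [c.area()]
        cfg = EngineConfig(dt=0.01, n_steps=20, biology=False)
        reaped = []
        for _ in range(600):
            run(w, cfg)
            if not reaped:
                areas.append(c.area())
            reaped = reap(w)
            if reaped:
                break
        assert reaped == [0]
        diffs = np.diff(areas)
        assert np.all(diffs < 0)

    def test_absorbing_no_growth_or_bonds(self, params20):
        w = World(seed=0)
        c = Cell.build(params20, cid=0)
        w.add_cell(c)
        start_apoptosis(c, w)
        with pytest.raises(StructuralError):
            add_growth_point(c, np.random.default_rng(0))
        res = run(w, EngineConfig(dt=0.01, n_steps=200))
        assert not any(e.kind in ("growth", "mitosis_start") for e in res.events)


class TestPolarization:
    def test_no_contact_unpolarized(self, cell40):
        polarize(cell40, np.zeros(cell40.n, dtype=bool))
        assert not cell40.polarized
        assert np.all(cell40.labels == 0)

    def test_bottom_contact_sector_labels(self, cell40):
        contact = cell40.mem_pos[:, 1] < -0.85 * cell40.params.radius
        polarize(cell40, contact)
        assert cell40.polarized
        labels = cell40.labels
        assert np.all(labels[contact] == LABEL_CODES["basal"])
        top = int(np.argmax(cell40.mem_pos[:, 1]))
        assert labels[top] == LABEL_CODES["apical"]
        side = int(np.argmax(cell40.mem_pos[:, 0]))
        assert labels[side] == LABEL_CODES["lateral"]

    def test_labels_partition_ring(self, cell40):
        contact = cell40.mem_pos[:, 1] < -0.85 * cell40.params.radius
        polarize(cell40, contact)
        counts = (
            (cell40.labels == LABEL_CODES["basal"]).sum()
            + (cell40.labels == LABEL_CODES["apical"]).sum()
            + (cell40.labels == LABEL_CODES["lateral"]).sum()
        )
        assert counts == cell40.n


class TestMotility:
    def test_phase_convention(self, cell40):
        block = enable_motility(cell40, direction=(1, 0), omega=0.5)
        motility_update(cell40, 0.0)
        assert np.allclose(cell40.radial.L0[block.anterior], block.L0_init_a)
        assert np.allclose(cell40.mem_drag[block.anterior], block.D_init_a)
        quarter = 0.5 * np.pi / 0.5  # omega*t = pi/2
        motility_update(cell40, quarter)
        assert np.allclose(cell40.radial.L0[block.anterior], block.L0_thresh_a)
        assert np.allclose(cell40.radial.L0[~block.anterior], block.L0_init_p)

    def test_full_period_no_drift(self, cell40):
        block = enable_motility(cell40, direction=(1, 0), omega=0.3)
        period = 2 * np.pi / 0.3
        for frac in np.linspace(0, 1, 7):
            motility_update(cell40, frac * period)
        motility_update(cell40, period)
        assert np.allclose(cell40.radial.L0[block.anterior], block.L0_init_a)
        assert np.allclose(cell40.radial.L0[~block.anterior], block.L0_init_p)
        assert np.allclose(cell40.mem_drag[block.anterior], block.D_init_a)

    def test_missing_labels_error(self, cell40):
        with pytest.raises(StructuralError):
            motility_update(cell40, 0.0)

    def test_net_crawling_displacement(self):
        import viscocell as vc

        w, cfg = vc.make_world(vc.ScenarioSpec("crawling_cell", {}, seed=0))
        cell = next(iter(w.cells.values()))
        x0 = cell.centroid()[0]
        omega = w.cells[0].motility.omega
        period = 2 * np.pi / omega
        cfg.n_steps = int(round(period / cfg.dt))
        run(w, cfg)
        assert cell.centroid()[0] > x0  # net forward motion per cycle
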