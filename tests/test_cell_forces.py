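import numpy as np
import pytest

from viscocell import (
    Cell,
    CellParams,
    World,
    cytoskeleton_forces,
    membrane_forces,
    nucleus_forces,
    pressure_forces,
    total_inner_force,
)
from viscocell.cell import StructuralError
from viscocell.engine import EngineConfig, run


class TestRestConfiguration:
    def test_all_operators_vanish_at_rest(self, rest_cell):
        assert np.allclose(cytoskeleton_forces(rest_cell), 0, atol=1e-12)
        assert np.allclose(nucleus_forces(rest_cell), 0, atol=1e-12)
        assert np.allclose(membrane_forces(rest_cell), 0, atol=1e-12)
        assert np.allclose(pressure_forces(rest_cell, 0.0), 0, atol=1e-12)

    def test_rest_geometry_is_fixed_point(self, rest_cell):
        """All elements at L0 and dP = 0: nothing moves over 1000 steps."""
        w = World(seed=0)
        w.add_cell(rest_cell)
        start = rest_cell.mem_pos.copy()
        run(w, EngineConfig(dt=0.01, n_steps=1000, biology=False))
        assert np.max(np.abs(rest_cell.mem_pos - start)) < 1e-8


class TestCytoskeleton:
    def test_displaced_nucleus_net_pull(self, rest_cell):
        rest_cell.nuc_pos[:, 0] += 0.1
        f_mem = cytoskeleton_forces(rest_cell)
        f_nuc = nucleus_forces(rest_cell)
        assert f_mem.sum(axis=0)[0] > 0  # membrane pulled toward +x nucleus
        # action-reaction across the radial elements (chords/ring still at rest
        # because the nucleus moved rigidly)
        assert np.allclose(f_mem.sum(axis=0), -f_nuc.sum(axis=0), atol=1e-9)

    def test_single_stretched_radial(self, rest_cell):
        i = 7
        axis = rest_cell.mem_pos[i] - rest_cell.nuc_pos[i]
        u = axis / np.linalg.norm(axis)
        delta = 0.25
        rest_cell.mem_pos[i] += delta * u
        f = cytoskeleton_forces(rest_cell)
        others = np.delete(np.arange(rest_cell.n), i)
        assert np.allclose(f[others], 0, atol=1e-9)
        k_r = rest_cell.radial.k[i]
        assert np.linalg.norm(f[i]) == pytest.approx(k_r * delta, rel=1e-9)


class TestNucleus:
    def test_uniform_nucleus_dilation_symmetric(self, rest_cell):
        center = rest_cell.nuc_pos.mean(axis=0)
        rest_cell.nuc_pos = center + 1.1 * (rest_cell.nuc_pos - center)
        f = nucleus_forces(rest_cell)
        # net zero by symmetry, each node pulled back toward the center
        assert np.allclose(f.sum(axis=0), 0, atol=1e-9)
        rel = rest_cell.nuc_pos - center
        assert np.all(np.einsum("ij,ij->i", f, rel) < 0)

    def test_chord_pairing_structure(self, cell40):
        n = cell40.n
        assert cell40.chord_partner(0) == n // 2
        # every node is the endpoint of exactly two chords
        counts = np.zeros(n)
        for i in range(n):
            counts[i] += 1
            counts[cell40.chord_partner(i)] += 1
        assert np.all(counts == 2)


class TestMembraneRing:
    def test_displaced_node_restoring(self, rest_cell):
        i = 3
        u = rest_cell.mem_pos[i] / np.linalg.norm(rest_cell.mem_pos[i])
        rest_cell.mem_pos[i] += 0.4 * u
        f = membrane_forces(rest_cell)
        assert f[i] @ u < 0  # pulled back inward toward its old position

    def test_uniform_dilation_inward_symmetric(self, rest_cell):
        rest_cell.mem_pos *= 1.2
        f = membrane_forces(rest_cell)
        rel = rest_cell.mem_pos
        assert np.all(np.einsum("ij,ij->i", f, rel) < 0)
        mags = np.linalg.norm(f, axis=1)
        assert np.allclose(mags, mags[0], rtol=1e-9)


class TestPressure:
    def test_closed_ring_sums_to_zero(self, cell40):
        cell40.P_in = 2.7
        f = pressure_forces(cell40, 0.3)
        scale = np.abs(f).sum()
        assert np.linalg.norm(f.sum(axis=0)) < 1e-9 * scale

    def test_unit_circle_node_magnitude(self):
        p = CellParams(n_points=40, radius=1.0, nucleus_radius=0.4, p_in=1.0)
        c = Cell.build(p, cid=0)
        f = pressure_forces(c, 0.0)
        expected = np.sin(2 * np.pi / 40)  # half neighbour-chord on the unit 40-gon
        assert np.allclose(np.linalg.norm(f, axis=1), expected, rtol=1e-9)
        assert expected == pytest.approx(0.157, abs=0.001)

    def test_no_differential_no_force(self, cell40):
        cell40.P_in = 0.8
        assert np.allclose(pressure_forces(cell40, 0.8), 0)


class TestTotalInnerForce:
    def test_perturbed_configuration_conserves(self, rest_cell, rng):
        rest_cell.mem_pos += rng.normal(0, 0.3, rest_cell.mem_pos.shape)
        rest_cell.nuc_pos += rng.normal(0, 0.1, rest_cell.nuc_pos.shape)
        rest_cell.P_in = 0.5
        f_mem, f_nuc = total_inner_force(rest_cell, p_env=0.0)
        total = f_mem.sum(axis=0) + f_nuc.sum(axis=0)
        scale = np.abs(f_mem).sum() + np.abs(f_nuc).sum()
        assert np.linalg.norm(total) < 1e-9 * scale

    def test_pressure_only_radial_outward(self, rest_cell):
        rest_cell.P_in = 1.0
        f_mem, f_nuc = total_inner_force(rest_cell, p_env=0.0)
        assert np.allclose(f_nuc, 0, atol=1e-12)
        rel = rest_cell.mem_pos / np.linalg.norm(rest_cell.mem_pos, axis=1)[:, None]
        assert np.all(np.einsum("ij,ij->i", f_mem, rel) > 0)


class TestNodeInsertion:
    def test_counts_and_rest_scaling(self, cell40):
        v0 = cell40.V_rest
        per0 = cell40.mem_el.L0.sum()
        cell40.insert_node(11, grow=True)
        assert cell40.n == 41
        assert len(cell40.nuc_pos) == 41
        for el in (cell40.mem_el, cell40.nucmem_el, cell40.radial, cell40.chord):
            assert len(el.k) == 41
        assert cell40.V_rest == pytest.approx(v0 * (41 / 40) ** 2)
        assert cell40.V_rest == pytest.approx(v0 * 1.0506, rel=1e-3)
        assert cell40.mem_el.L0.sum() == pytest.approx(per0 * 41 / 40)

    def test_structural_validation(self, cell40):
        cell40.insert_node(0, grow=False)
        cell40.validate()

    def test_ring_mismatch_detected(self, cell40):
        cell40.nuc_pos = cell40.nuc_pos[:-1]
        with pytest.raises(StructuralError):
            cell40.validate()
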