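import json

import numpy as np
import pytest
from click.testing import CliRunner

import viscocell as vc
from viscocell.cli import main as cli_main
from viscocell.engine import run
from viscocell.frames import FrameParseError, read_frame, write_frame
from viscocell.processes import partition_cell, select_division_axis
from viscocell.scenarios import (
    SCENARIO_NAMES,
    ScenarioSpec,
    gap_regime_classifier,
    list_scenarios,
    make_world,
)


class TestConstruction:
    def test_single_cell_counts(self):
        w, _ = make_world(ScenarioSpec("single_cell"))
        (cell,) = w.cells.values()
        assert cell.n == 40
        nodes = list(cell.iter_nodes())
        assert len(nodes) == 80  # 40 membrane + 40 nucleus
        elements = list(cell.iter_elements())
        assert len(elements) == 160  # 40 per category
        cats = {e.category for e in elements}
        assert cats == {"membrane", "nuclear_membrane", "radial", "nuclear_chord"}

    def test_monolayer_starts_from_two_cells(self):
        w, _ = make_world(ScenarioSpec("monolayer"))
        assert len(w.cells) == 2
        assert w.t == 0.0

    def test_gap_width_parameter(self):
        w, _ = make_world(ScenarioSpec("ecm_gap", {"gap_width_R": 2.0}))
        chain = next(iter(w.ecm_chains.values()))
        R = 7.5
        assert np.any(np.isclose(chain.pos[:, 0], -R, atol=1e-6))
        assert np.any(np.isclose(chain.pos[:, 0], R, atol=1e-6))
        assert chain.rigid

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bogus")

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            make_world(ScenarioSpec("monolayer", {"frobnicate": 1}))

    @pytest.mark.parametrize("name", SCENARIO_NAMES)
    def test_smoke_100_steps(self, name):
        """Every named scenario constructs and survives 100 steps."""
        w, cfg = make_world(ScenarioSpec(name, seed=1))
        cfg.n_steps = 100
        run(w, cfg)
        w.validate()
        assert len(w.cells) >= 1


class TestFrames:
    def test_round_trip_single_cell(self, tmp_path):
        w, cfg = make_world(ScenarioSpec("single_cell", seed=5))
        cfg.n_steps = 50
        run(w, cfg)
        path = tmp_path / "frame.tsv"
        write_frame(w, path)
        w2 = read_frame(path)
        c1 = w.cells[0]
        c2 = w2.cells[0]
        assert np.array_equal(c1.mem_pos, c2.mem_pos)
        assert np.array_equal(c1.nuc_pos, c2.nuc_pos)
        assert np.array_equal(c1.mem_el.L0, c2.mem_el.L0)
        assert c1.V_rest == c2.V_rest
        assert w2.t == w.t

    def test_round_trip_mitotic_cell(self, tmp_path):
        w, _ = make_world(ScenarioSpec("single_cell", seed=5))
        cell = w.cells[0]
        st = partition_cell(cell, select_division_axis(cell))
        path = tmp_path / "mitotic.tsv"
        write_frame(w, path)
        w2 = read_frame(path)
        st2 = w2.cells[0].mitosis
        assert st2 is not None
        assert np.array_equal(st.order_a, st2.order_a)
        assert np.allclose(st.u, st2.u)
        assert w2.cells[0].chord is None

    def test_round_trip_with_ecm_and_bonds(self, tmp_path):
        w, cfg = make_world(ScenarioSpec("ecm_line_epithelium", seed=2))
        cfg.n_steps = 200
        run(w, cfg)
        assert len(w.bonds) > 0
        path = tmp_path / "ep.tsv"
        write_frame(w, path)
        w2 = read_frame(path)
        assert set(w2.bonds) == set(w.bonds)
        eid = next(iter(w.ecm_chains))
        assert np.array_equal(w.ecm_chains[eid].pos, w2.ecm_chains[eid].pos)

    def test_truncated_file_rejected(self, tmp_path):
        w, _ = make_world(ScenarioSpec("single_cell"))
        path = tmp_path / "frame.tsv"
        write_frame(w, path)
        text = path.read_text().splitlines()
        (tmp_path / "cut.tsv").write_text("\n".join(text[: len(text) // 2]))
        with pytest.raises(FrameParseError):
            read_frame(tmp_path / "cut.tsv")


class TestCli:
    def test_list_scenarios(self):
        res = CliRunner().invoke(cli_main, ["--list-scenarios"])
        assert res.exit_code == 0
        assert len(res.output.split()) == 9

    def test_unknown_scenario_usage_error(self):
        res = CliRunner().invoke(
            cli_main, ["--scenario", "bogus", "--out", "x"]
        )
        assert res.exit_code == 2

    def test_missing_out_usage_error(self):
        res = CliRunner().invoke(cli_main, ["--scenario", "single_cell"])
        assert res.exit_code == 2

    def test_short_run_writes_outputs(self, tmp_path):
        out = tmp_path / "run"
        res = CliRunner().invoke(
            cli_main,
            [
                "--scenario", "single_cell", "--steps", "40", "--seed", "3",
                "--out", str(out), "--metrics-every", "10",
            ],
        )
        assert res.exit_code == 0, res.output
        assert (out / "final_frame.tsv").exists()
        assert (out / "events.tsv").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["scenario"] == "single_cell"
        assert manifest["seed"] == 3

    def test_seed_changes_events(self, tmp_path):
        logs = []
        for seed in (1, 2):
            out = tmp_path / f"s{seed}"
            res = CliRunner().invoke(
                cli_main,
                ["--scenario", "monolayer", "--steps", "1500",
                 "--seed", str(seed), "--out", str(out),
                 "--param", "drag=0.0005"],
            )
            assert res.exit_code == 0, res.output
            logs.append((out / "events.tsv").read_text())
        header = logs[0].splitlines()[0]
        assert logs[1].splitlines()[0] == header  # same schema
        assert logs[0] != logs[1]                 # different realizations


class TestGapClassifier:
    def test_empty_notch_not_lined(self):
        w, _ = make_world(ScenarioSpec("ecm_gap", {"gap_width_R": 2.0}))
        w.cells.clear()
        assert gap_regime_classifier(w, W=15.0, R=7.5) == "not_lined"

    def test_cells_above_mouth_not_lined(self):
        w, _ = make_world(ScenarioSpec("ecm_gap", {"gap_width_R": 2.0}))
        # founder cells sit on the line left of the gap, above the mouth
        assert gap_regime_classifier(w, W=15.0, R=7.5) == "not_lined"


class TestTensegrity:
    @pytest.mark.parametrize("seed", [1, 4])
    def test_deflection_localizes_in_thinned_region(self, seed):
        """Matrix deflection under a growing monolayer concentrates where the
        matrix is thinned (the central low-drag dip)."""
        from viscocell.scenarios import max_ecm_deflection

        w, cfg = make_world(
            ScenarioSpec("tensegrity_bud", {"dip_depth": 0.9}, seed=seed)
        )
        cfg.n_steps = 3000
        run(w, cfg)
        chain = next(iter(w.ecm_chains.values()))
        assert max_ecm_deflection(w) > 0.2
        lowest_x = float(chain.pos[np.argmin(chain.pos[:, 1]), 0])
        sigma = 8.0  # scenario default dip width
        assert abs(lowest_x) <= 2 * sigma
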