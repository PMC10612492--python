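"""Model facade, scenario response, pipeline determinism, CLI plumbing."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import sentinet as sn
from sentinet.cli import main as cli_main
from sentinet.pipeline import RunConfig, run_pipeline


class TestModelFacade:
    def test_fit_exposes_estimates(self, fitted):
        assert fitted.mper > 0
        assert fitted.mper_se >= 0
        assert fitted.n_pairs + fitted.excluded_pairs == len(fitted.pairwise.nodes) * (
            len(fitted.pairwise.nodes) - 1
        ) // 2
        assert fitted.isolation.index.name == "park_id"
        assert fitted.resistances.shape == (15, 15)

    def test_summary_reports_headline_numbers(self, fitted):
        text = fitted.summary()
        assert "MPER" in text and f"{fitted.mper:.6g}" in text
        assert "8-neighbor" in text

    def test_refit_is_deterministic(self, small_landscape, small_parks):
        a = sn.SentinelNetwork.from_parks(small_landscape, small_parks).fit()
        b = sn.SentinelNetwork.from_parks(small_landscape, small_parks).fit()
        assert a.mper == b.mper
        np.testing.assert_array_equal(a.current_map, b.current_map)

    def test_development_edit_raises_mper_park_edit_lowers(self, fitted):
        model = fitted.model
        dev = sn.generate_scenario_footprints("development", 5.0, "low", model.cost, seed=21)
        park = sn.generate_scenario_footprints("park", 5.0, "high", model.cost, seed=22)
        assert model.with_edit(dev).fit().compare(fitted) >= 0
        assert model.with_edit(park).fit().compare(fitted) <= 0

    def test_non_node_park_reduces_mper(self, fitted):
        """A new protected area helps connectivity even when it is not a node."""
        model = fitted.model
        node_cells = {nd.cell for nd in model.nodes}
        edit = sn.generate_scenario_footprints("park", 8.0, "moderate", model.cost, seed=23)
        away = frozenset(set(edit.cells) - node_cells)
        assert away  # footprint still has cells after avoiding the nodes
        edit = sn.ScenarioEdit(mode="park", cells=away, name="non-node park")
        assert model.with_edit(edit).fit().compare(fitted) <= 0

    def test_comparing_different_node_sets_refused(self, small_landscape, small_parks):
        full = sn.SentinelNetwork.from_parks(small_landscape, small_parks).fit()
        subset = sn.SentinelNetwork.from_parks(
            small_landscape, small_parks, sentinel_ids=small_parks.ids[:10]
        ).fit()
        with pytest.raises(ValueError, match="sentinel"):
            subset.compare(full)


@pytest.fixture
def pipeline_cfg(tmp_path):
    return RunConfig(
        output_dir=str(tmp_path / "out"),
        synthetic={
            "landscape": {"shape": [40, 40]},
            "parks": {"n_parks": 8, "min_spacing": 1500.0},
        },
        scenarios=[{"mode": "development", "area_km2": 3.0, "context": "low"}],
        seed=5,
    )


class TestPipeline:
    def test_outputs_written_and_rerun_identical(self, pipeline_cfg, tmp_path):
        out1 = run_pipeline(pipeline_cfg)
        csv1 = (tmp_path / "out" / "node_isolation.csv").read_bytes()
        scen1 = (tmp_path / "out" / "scenario_table.csv").read_bytes()
        # second run re-loads the stored sentinel set: byte-identical tables
        out2 = run_pipeline(pipeline_cfg)
        assert (tmp_path / "out" / "node_isolation.csv").read_bytes() == csv1
        assert (tmp_path / "out" / "scenario_table.csv").read_bytes() == scen1
        assert out1["mper_ohms"] == out2["mper_ohms"]
        assert (tmp_path / "out" / "provenance.json").exists()

    def test_scenario_block_adds_delta_column(self, pipeline_cfg, tmp_path):
        result = run_pipeline(pipeline_cfg)
        assert "delta_mper" in result["scenarios"][0]
        assert result["scenarios"][0]["delta_mper"] >= 0  # development

    def test_missing_parks_file_names_path(self, tmp_path):
        cfg = RunConfig(
            output_dir=str(tmp_path / "o"),
            cost_raster=None,
            parks=str(tmp_path / "absent.geojson"),
        )
        with pytest.raises(RuntimeError, match="cost"):
            run_pipeline(cfg)

    def test_resolution_mismatch_warns(self, pipeline_cfg):
        pipeline_cfg.baseline_resolution = 600.0
        with pytest.warns(UserWarning, match="resolution"):
            run_pipeline(pipeline_cfg)


class TestCli:
    def test_simulate_then_pairwise(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(
            cli_main,
            ["simulate", "--out", str(tmp_path), "--shape", "30", "30", "--n-parks", "6", "--seed", "2"],
        )
        assert sim.exit_code == 0, sim.output
        # place nodes from the generated parks, then run the pairwise command
        cost = sn.generate_landscape(sn.LandscapeSpec(shape=(30, 30), seed=2))
        parks = sn.fileio.read_parks_geojson(tmp_path / "parks.geojson")
        surface = sn.apply_protection_overlay(cost, parks)
        nodes = [sn.place_node(p, surface) for p in parks]
        sn.fileio.write_nodes_csv(nodes, tmp_path / "nodes.csv", surface)
        sn.fileio.write_raster(surface, tmp_path / "surface.asc")
        run = runner.invoke(
            cli_main,
            [
                "run-pairwise",
                "--cost", str(tmp_path / "surface.asc"),
                "--nodes", str(tmp_path / "nodes.csv"),
                "--out", str(tmp_path / "pw"),
            ],
        )
        assert run.exit_code == 0, run.output
        report = json.loads((tmp_path / "pw" / "indicators.json").read_text())
        assert report["mper_ohms"] > 0
        assert (tmp_path / "pw" / "current_density.asc").exists()

    def test_bad_input_exits_with_data_code(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["build-cost", "--cost", str(tmp_path / "x.asc"), "--parks", str(tmp_path / "y"), "--out", "z"],
        )
        assert res.exit_code == 2  # click: path does not exist

    def test_run_subcommand_from_yaml(self, tmp_path):
        cfg = {
            "output_dir": str(tmp_path / "run-out"),
            "synthetic": {"landscape": {"shape": [30, 30]}, "parks": {"n_parks": 6}},
            "seed": 3,
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        res = CliRunner().invoke(cli_main, ["run", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert "mper_ohms" in res.output
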