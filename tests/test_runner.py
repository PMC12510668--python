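"""Configuration, orchestration, persistence and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from placeremap import cli, runner
from placeremap.runner import ConfigError, ScenarioConfig


def toy_multichart(**overrides):
    """The small end-to-end configuration: N=24, Y=3, Z=2, K=2, 1-d grid."""
    params = dict(
        kind="multi_chart", N=24, Y=3, P=1, C=0, K=2, grid_resolution=40, seed=5
    )
    params.update(overrides)
    return ScenarioConfig(**params)


class TestScenarioConfig:
    def test_multichart_requires_no_cognitive(self):
        with pytest.raises(ConfigError, match="C = 0"):
            ScenarioConfig(kind="multi_chart", Y=8, C=2)

    def test_implicit_space_rejects_position(self):
        with pytest.raises(ConfigError, match="P = 0"):
            ScenarioConfig(kind="implicit_space", P=2, C=3)

    def test_gridrealign_forces_y_equals_z(self):
        cfg = ScenarioConfig(kind="grid_realign", m=3, P=2, N=96)
        assert cfg.Y == cfg.Z == 12
        with pytest.raises(ConfigError, match="Y = Z"):
            ScenarioConfig(kind="grid_realign", m=3, P=2, N=96, Y=16)

    def test_default_frequency_exponents_filled(self):
        cfg = ScenarioConfig(kind="grid_realign", m=3, P=1, N=48)
        assert cfg.f == (0, 1, -1)

    def test_sigma_validation(self):
        with pytest.raises(ConfigError, match="sigma"):
            ScenarioConfig(kind="space_feature", P=1, C=1, N=16, sigma=1.5)

    def test_full_d_defaults(self):
        cfg = ScenarioConfig(kind="multi_chart", full_d=True, N=32, P=1)
        assert cfg.Y == 32 and cfg.code == "identity"

    def test_reward_environment_count_must_match_locations(self):
        with pytest.raises(ConfigError, match="reward_mu"):
            ScenarioConfig(kind="reward", P=1, C=1, N=16, K=3, reward_mu=(0.0, 0.5))


class TestParseConfig:
    def test_yaml_roundtrip_with_defaults(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"kind": "multi_chart", "Y": 8, "N": 64}))
        cfg = runner.parse_config(path)
        assert cfg.kind == "multi_chart"
        assert cfg.n_shuffle == 20
        assert cfg.field_fraction == 0.1
        assert cfg.grid_resolution == 32  # 2-d default

    def test_json_config(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"kind": "grid_realign", "m": 3, "P": 1, "N": 48}))
        cfg = runner.parse_config(path)
        assert cfg.f == (0, 1, -1)

    def test_missing_kind_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"N": 64}))
        with pytest.raises(ConfigError, match="kind"):
            runner.parse_config(path)

    def test_unknown_key_warns(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            yaml.safe_dump({"kind": "multi_chart", "Y": 8, "N": 64, "bogus": 1})
        )
        with pytest.warns(UserWarning, match="bogus"):
            runner.parse_config(path)

    def test_invalid_value_names_key(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            yaml.safe_dump({"kind": "space_feature", "P": 1, "C": 1, "N": 16, "sigma": 2.0})
        )
        with pytest.raises(ConfigError, match="sigma"):
            runner.parse_config(path)


class TestRunScenario:
    def test_toy_multichart_end_to_end(self):
        record = runner.run_scenario(toy_multichart())
        assert len(record.ratemaps) == 2
        assert record.stats is not None and len(record.stats.pairs) == 1
        assert record.ratemaps[0].rates.shape == (24, 40)
        assert np.all(record.ratemaps[0].rates >= 0)

    def test_environment_maps_differ_between_environments(self):
        record = runner.run_scenario(toy_multichart())
        maps = record.extras["embedding_maps"]
        assert not np.allclose(maps[0].R, maps[1].R)

    def test_identical_seed_reproduces_rates(self):
        a = runner.run_scenario(toy_multichart())
        b = runner.run_scenario(toy_multichart())
        for ra, rb in zip(a.ratemaps, b.ratemaps):
            np.testing.assert_array_equal(ra.rates, rb.rates)

    def test_different_seed_differs(self):
        a = runner.run_scenario(toy_multichart())
        b = runner.run_scenario(toy_multichart(seed=6))
        assert not np.allclose(a.ratemaps[0].rates, b.ratemaps[0].rates)

    def test_adding_environment_preserves_earlier_ones(self):
        a = runner.run_scenario(toy_multichart(K=2))
        b = runner.run_scenario(toy_multichart(K=3))
        np.testing.assert_array_equal(a.ratemaps[0].rates, b.ratemaps[0].rates)
        np.testing.assert_array_equal(a.ratemaps[1].rates, b.ratemaps[1].rates)


class TestPersistence:
    def test_round_trip_preserves_stats(self, tmp_path):
        record = runner.run_scenario(toy_multichart())
        out = runner.persist_results(record, tmp_path / "run")
        data = runner.load_run(out)
        np.testing.assert_array_equal(
            data["rates"]["env0"], record.ratemaps[0].rates
        )
        assert data["stats"]["overlap"].iloc[0] == pytest.approx(
            record.stats.omega[0], abs=1e-12
        )

    def test_manifest_checksums_every_file(self, tmp_path):
        record = runner.run_scenario(toy_multichart())
        out = runner.persist_results(record, tmp_path / "run")
        manifest = json.loads((out / "manifest.json").read_text())
        for name in manifest["files"]:
            assert (out / name).exists()
        assert "stats.csv" in manifest["files"]

    def test_version_mismatch_warns_but_loads(self, tmp_path):
        record = runner.run_scenario(toy_multichart())
        out = runner.persist_results(record, tmp_path / "run")
        manifest = json.loads((out / "manifest.json").read_text())
        manifest["version"] = "0.0.0"
        (out / "manifest.json").write_text(json.dumps(manifest))
        with pytest.warns(UserWarning, match="version"):
            runner.load_run(out)

    def test_byte_identical_stats_csv(self, tmp_path):
        out1 = runner.persist_results(
            runner.run_scenario(toy_multichart()), tmp_path / "a"
        )
        out2 = runner.persist_results(
            runner.run_scenario(toy_multichart()), tmp_path / "b"
        )
        assert (out1 / "stats.csv").read_bytes() == (out2 / "stats.csv").read_bytes()

    def test_analyze_from_disk_matches_in_process(self, tmp_path):
        record = runner.run_scenario(toy_multichart())
        out = runner.persist_results(record, tmp_path / "run")
        frame = runner.analyze_run(out)
        np.testing.assert_allclose(
            frame["overlap"].to_numpy(), record.stats.omega, atol=1e-12
        )
        np.testing.assert_allclose(
            frame["overlap_shuffle"].to_numpy(), record.stats.omega_shuffle, atol=1e-12
        )


class TestCli:
    def test_simulate_analyze_report_compose(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            yaml.safe_dump(
                dict(kind="multi_chart", N=24, Y=3, P=1, K=2, grid_resolution=40, seed=5)
            )
        )
        out = tmp_path / "out"
        cli_runner = CliRunner()
        res = cli_runner.invoke(cli.main, ["simulate", "--config", str(cfg), "--out", str(out)])
        assert res.exit_code == 0, res.output
        res = cli_runner.invoke(cli.main, ["analyze", "--in", str(out)])
        assert res.exit_code == 0, res.output
        frame = pd.read_csv(out / "stats.csv")
        # analyze on persisted rate maps reproduces the persisted statistics
        reanalyzed = float(res.output.splitlines()[1].split(",")[2])
        assert reanalyzed == pytest.approx(frame["overlap"].iloc[0], abs=1e-10)
        res = cli_runner.invoke(cli.main, ["report", "--in", str(out)])
        assert res.exit_code == 0, res.output
        assert "overlap_mean" in res.output
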