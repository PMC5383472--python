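"""Experiment drivers, fixture generation, configs and the command line."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import exposim as ex
from exposim.cli import main as cli_main
from exposim.scenarios import (
    ExperimentSpec,
    default_config,
    default_environment,
    generate_fixtures,
    load_experiment,
    run_aversion_sweep,
    run_constrained_movement,
    run_weighting_comparison,
    write_run_log,
)


@pytest.fixture(scope="module")
def small_env():
    return default_environment(radius_km=40.0, cell_km=5.0)


def small_spec(experiment, **over):
    base = default_config(
        n_agents=over.pop("n_agents", 80),
        duration_h=over.pop("duration_h", 2.0),
        dt_s=over.pop("dt_s", 120.0),
        seed=over.pop("seed", 5),
        **over,
    )
    return ExperimentSpec(experiment, base, durations_h=(1.0, 2.0))


class TestFixtures:
    def test_generation_is_deterministic(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for d in (a, b):
            generate_fixtures(d)
        for fa in sorted(a.iterdir()):
            assert fa.read_bytes() == (b / fa.name).read_bytes()

    def test_bathymetry_fixture_is_uniform_50m(self, tmp_path):
        generate_fixtures(tmp_path)
        df = pd.read_csv(tmp_path / "bathymetry_flat.csv")
        assert (df["depth_m"] == 50.0).all()

    def test_configs_echo_study_conditions(self, tmp_path):
        generate_fixtures(tmp_path)
        for stem in ("weighting", "aversion", "constrained"):
            cfg = yaml.safe_load((tmp_path / f"{stem}.yaml").read_text())
            assert cfg["source"]["source_level_db"] == 240.0
            assert cfg["source"]["frequency_khz"] == 1.0
            assert cfg["source"]["duty_cycle"] == 0.1
            assert cfg["propagation"]["k"] == 15.0
            assert cfg["n_agents"] == 10000

    def test_config_roundtrip(self, tmp_path):
        generate_fixtures(tmp_path)
        spec = load_experiment(tmp_path / "aversion.yaml")
        assert spec.experiment == "aversion_sweep"
        assert spec.sweep == (10.0, 1.0, 0.5, 0.1, 0.05)
        assert spec.base.source.duty_cycle == 0.1

    def test_density_table_roundtrip(self, tmp_path):
        generate_fixtures(tmp_path)
        df = pd.read_csv(tmp_path / "density_disc.csv")
        grid = ex.DensityGrid.from_frame(df)
        assert ex.abundance(grid) == pytest.approx(0.05 * np.pi * 100.0**2, rel=0.05)


class TestWeightingComparison:
    def test_a_rows_are_zero_and_m_curve_above(self, small_env):
        spec = small_spec("weighting_comparison")
        table, curves = run_weighting_comparison(spec, small_env)
        a_rows = table[table["scheme"] == "A"]
        for col in ("pct_1h", "pct_2h"):
            assert (a_rows[col] == 0.0).all()
        for name in ("gray seal", "harbor porpoise"):
            m = curves[(name, "M")]["mean_sel_db"].to_numpy()
            a = curves[(name, "A")]["mean_sel_db"].to_numpy()
            assert np.all(m > a + 10.0)  # separation is tens of dB

    def test_unknown_species_rejected(self, small_env):
        spec = small_spec("weighting_comparison")
        spec.sweep = ("krill",)
        with pytest.raises(ValueError, match="unknown species"):
            run_weighting_comparison(spec, small_env)


class TestAversionSweep:
    def test_difference_table_uses_extreme_arms(self, small_env):
        spec = small_spec("aversion_sweep")
        spec.sweep = (10.0, 0.05)
        curves, diffs = run_aversion_sweep(spec, small_env)
        assert set(curves) == {10.0, 0.05}
        assert (diffs["sd_high"] == 10.0).all()
        assert (diffs["sd_low"] == 0.05).all()
        # directionless agents accumulate at least as much as fleeing ones
        assert (diffs["delta_db"] >= 0).all()

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ExperimentSpec("aversion_sweep", default_config(), sweep=(-1.0,))


class TestConstrainedMovement:
    def test_constrained_at_least_unconstrained(self, small_env):
        spec = small_spec("constrained_movement")
        spec.sweep = ((30.0, 0.5),)
        curves, diffs = run_constrained_movement(spec, small_env)
        assert (diffs["delta_db"] >= -1e-9).all()
        con = curves[(30.0, 0.5, "constrained")]["mean_sel_db"].to_numpy()
        unc = curves[(30.0, 0.5, "unconstrained")]["mean_sel_db"].to_numpy()
        assert np.all(con >= unc - 1e-9)

    def test_boundary_beyond_extent_rejected(self, small_env):
        spec = small_spec("constrained_movement")
        spec.sweep = ((500.0, 0.5),)
        with pytest.raises(ValueError, match="extent"):
            run_constrained_movement(spec, small_env)


class TestRunLogAndCli:
    def test_run_log_contents(self, tmp_path):
        spec = small_spec("aversion_sweep")
        path = write_run_log(tmp_path, spec)
        log = json.loads(path.read_text())
        assert log["seed"] == spec.base.seed
        assert log["config"]["source"]["source_level_db"] == 240.0
        assert log["version"] == ex.__version__

    def test_cli_fixtures_and_run(self, tmp_path):
        runner = CliRunner()
        fix_dir = tmp_path / "fix"
        res = runner.invoke(cli_main, ["fixtures", "--out", str(fix_dir)])
        assert res.exit_code == 0, res.output
        out_dir = tmp_path / "out"
        res = runner.invoke(
            cli_main,
            [
                "run", str(fix_dir / "aversion.yaml"),
                "--seed", "3", "--n-agents", "40", "--dt", "300",
                "--duration", "1", "--out", str(out_dir),
            ],
        )
        assert res.exit_code == 0, res.output
        assert (out_dir / "aversion_differences.csv").exists()
        assert (out_dir / "run_log.json").exists()
        log = json.loads((out_dir / "run_log.json").read_text())
        assert log["seed"] == 3 and log["config"]["n_agents"] == 40

    def test_identical_seed_and_config_identical_outputs(self, tmp_path):
        runner = CliRunner()
        fix_dir = tmp_path / "fix"
        runner.invoke(cli_main, ["fixtures", "--out", str(fix_dir)])
        outs = []
        for sub in ("o1", "o2"):
            res = runner.invoke(
                cli_main,
                [
                    "run", str(fix_dir / "aversion.yaml"),
                    "--seed", "7", "--n-agents", "30", "--dt", "300",
                    "--duration", "1", "--out", str(tmp_path / sub),
                ],
            )
            assert res.exit_code == 0, res.output
            outs.append((tmp_path / sub / "aversion_differences.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_cli_summarize(self, tmp_path, gray_seal):
        env = default_environment(radius_km=40.0)
        cfg = default_config(n_agents=30, duration_h=1.0, seed=2)
        hist = ex.run_simulation(cfg, gray_seal, env)
        hist_file = tmp_path / "hist.csv"
        hist.to_frame().to_csv(hist_file, index=False)
        runner = CliRunner()
        res = runner.invoke(
            cli_main, ["summarize", str(hist_file), "--threshold", "203"]
        )
        assert res.exit_code == 0, res.output
        assert "mean_sel_db" in res.output
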