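import json

import numpy as np
import pytest
from click.testing import CliRunner

from wqbench.cli import main as cli_main
from wqbench.report import (
    ExperimentConfig,
    derive_seed,
    read_series_csv,
    run_experiment,
)
from wqbench.synthetic_data import generate_population, preset_scenario

SMALL = dict(presets=("good_near_boundary",), schemes=("OM",), reps=50, n_draws=100, seed=1)


class TestExperimentConfig:
    def test_defaults_mirror_regulatory_protocol(self):
        config = ExperimentConfig()
        assert config.reps == 10_000
        assert config.n_draws == 1000
        assert config.alpha == 0.01
        assert set(config.schemes) == {"OM", "SM"}

    def test_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(reps=0)
        with pytest.raises(ValueError):
            ExperimentConfig(methods=("pca",))
        with pytest.raises(KeyError):
            ExperimentConfig(presets=("nope",))
        with pytest.raises(FileNotFoundError):
            ExperimentConfig(csv_paths=("/no/such.csv",))

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(ExperimentConfig(**SMALL).to_dict()))
        assert ExperimentConfig.from_yaml(path) == ExperimentConfig(**SMALL)


class TestDeriveSeed:
    def test_stable_distinct_and_bounded(self):
        a = derive_seed(1, "pop", "OM", 3)
        assert a == derive_seed(1, "pop", "OM", 3)
        assert a != derive_seed(1, "pop", "OM", 4)
        assert a != derive_seed(2, "pop", "OM", 3)
        assert 0 <= a < 2**31


class TestReadSeriesCsv:
    def test_error_reports_offending_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "timestamp,concentration_mgP_L\n"
            "2011-01-01T00:00:00,0.02\n"
            "2011-01-01T01:00:00,-0.5\n"
        )
        with pytest.raises(ValueError, match="rows 3"):
            read_series_csv(path)

    def test_empty_and_wrong_header(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("timestamp,concentration_mgP_L\n")
        with pytest.raises(ValueError, match="empty"):
            read_series_csv(empty)
        wrong = tmp_path / "wrong.csv"
        wrong.write_text("time,conc\n1,2\n")
        with pytest.raises(ValueError, match="header"):
            read_series_csv(wrong)


class TestRunExperiment:
    def test_smoke_report_is_complete(self, tmp_path):
        report = run_experiment(ExperimentConfig(**SMALL), out_dir=tmp_path / "out")
        section = report["populations"]["good_near_boundary"]["schemes"]["OM"]
        assert set(section["sampling"]) == {"mean", "q95"}
        assert set(section["second_order"]) == {"lognormal", "bayesian_bootstrap"}
        assert set(section["classification"]) == {
            "face_value", "t_test_right", "t_test_left", "lognormal", "bayesian_bootstrap"
        }
        for method, c in section["classification"].items():
            freqs = c["frequencies"]
            assert sum(freqs.values()) == pytest.approx(100.0)
        for name in ("report.json", "sampling_summary.csv",
                     "second_order_summary.csv", "classification_summary.csv"):
            assert (tmp_path / "out" / name).exists()

    def test_same_config_and_seed_give_byte_identical_reports(self):
        a = run_experiment(ExperimentConfig(**SMALL))
        b = run_experiment(ExperimentConfig(**SMALL))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_two_presets_two_schemes_compose(self):
        config = ExperimentConfig(
            presets=("good_near_boundary", "moderate_far"),
            schemes=("OM", "SM"), reps=40, n_draws=100, seed=2,
            methods=("face_value", "lognormal"),
        )
        report = run_experiment(config)
        assert set(report["populations"]) == {"good_near_boundary", "moderate_far"}
        for pop in report["populations"].values():
            assert set(pop["schemes"]) == {"OM", "SM"}

    def test_increasing_reps_preserves_early_replicates(self, good_pop):
        # counter-based sub-seeds: the first replicates must not reshuffle
        from wqbench.subsampling import OM, draw_subsamples
        small = draw_subsamples(good_pop, OM, reps=10, seed=derive_seed(1, "x", "OM", "subsample"))
        large = draw_subsamples(good_pop, OM, reps=200, seed=derive_seed(1, "x", "OM", "subsample"))
        for s, l in zip(small, large[:10]):
            np.testing.assert_array_equal(s.indices, l.indices)

    def test_user_supplied_csv_population(self, tmp_path):
        series = generate_population(
            preset_scenario("moderate_far").spec, 2000, seed=3
        )
        path = tmp_path / "site.csv"
        series.to_csv(path)
        config = ExperimentConfig(
            presets=(), csv_paths=(str(path),), schemes=("OM",),
            reps=40, n_draws=100, seed=4, methods=("face_value",),
        )
        report = run_experiment(config)
        assert "site" in report["populations"]
        assert report["populations"]["site"]["benchmark"]["status"] == "Moderate"


class TestCli:
    def test_simulate_fit_classify_pipeline(self, tmp_path):
        runner = CliRunner()
        out_csv = str(tmp_path / "series.csv")
        result = runner.invoke(cli_main, [
            "simulate", "--preset", "good_near_boundary",
            "--n-hours", "2000", "--seed", "5", "--out", out_csv,
        ])
        assert result.exit_code == 0, result.output

        result = runner.invoke(cli_main, ["fit", "--series", out_csv, "--family", "lognormal"])
        assert result.exit_code == 0, result.output
        assert json.loads(result.output)["family"] == "lognormal"

        result = runner.invoke(cli_main, ["classify", "--sample", out_csv])
        assert result.exit_code == 0, result.output
        assert json.loads(result.output)["status"] in ("High", "Good", "Moderate")

    def test_subsample_infer_and_run_all(self, tmp_path):
        runner = CliRunner()
        out_csv = str(tmp_path / "series.csv")
        runner.invoke(cli_main, ["simulate", "--n-hours", "2000", "--seed", "1",
                                 "--out", out_csv])
        result = runner.invoke(cli_main, [
            "subsample", "--series", out_csv, "--scheme", "SM", "--reps", "200",
            "--statistic", "q95", "--out", str(tmp_path / "draws.csv"),
        ])
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, [
            "infer", "--sample", out_csv, "--method", "bayesian_bootstrap",
            "--draws", "200", "--out", str(tmp_path / "post.csv"),
        ])
        assert result.exit_code == 0, result.output

        import yaml
        config_path = tmp_path / "config.yaml"
        config_path.write_text(yaml.safe_dump({
            "presets": ["good_near_boundary"], "schemes": ["OM"],
            "methods": ["face_value", "lognormal"], "n_hours": 2000,
        }))
        result = runner.invoke(cli_main, [
            "run-all", "--config", str(config_path), "--seed", "1",
            "--reps", "45", "--draws", "100", "--out-dir", str(tmp_path / "report"),
        ])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "report" / "report.json").exists()
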