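import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from conftest import make_record
from pembropred.cli import main
from pembropred.errors import ConfigError, ParseError
from pembropred.workflow import (RunConfig, covariate_frame, read_cohort,
                                 run_fit_stage, run_predict_stage,
                                 run_train_stage, write_cohort_csvs)


@pytest.fixture(scope="module")
def fit_result(noise_free_cohort):
    config = RunConfig()
    fitted, table, metrics = run_fit_stage(noise_free_cohort.records, config)
    return config, fitted, table, metrics


class TestFitStage:
    def test_noise_free_confusion_is_diagonal(self, fit_result):
        _, _, table, metrics = fit_result
        assert (table["fit_interval"] == table["obs_interval"]).all()
        assert metrics["fit_vs_observed"]["kappa"]["kappa"] == pytest.approx(1.0)
        assert metrics["r2_linear"] >= 0.99

    def test_outputs_are_deterministic(self, tmp_path, noise_free_cohort):
        config = RunConfig()
        for d in ("a", "b"):
            run_fit_stage(noise_free_cohort.records, config,
                          outdir=tmp_path / d)
        assert (tmp_path / "a" / "fitted_params.csv").read_bytes() == \
               (tmp_path / "b" / "fitted_params.csv").read_bytes()

    def test_csv_round_trip(self, tmp_path, fit_result):
        config, _, table, _ = fit_result
        table.to_csv(tmp_path / "fitted_params.csv")
        back = pd.read_csv(tmp_path / "fitted_params.csv").set_index("patient_id")
        pd.testing.assert_frame_equal(back, table, check_dtype=False)


class TestTrainStage:
    def test_screening_and_loo_outputs(self, noise_free_cohort, fit_result):
        config, _, table, _ = fit_result
        metrics = run_train_stage(noise_free_cohort.records, table, config)
        assert "screen" in metrics and "gamma_tree" in metrics
        assert metrics["gamma_tree"]["confusion"]["n"] == len(table)

    def test_loo_predictions_carry_signal_on_default_cohorts(self):
        """Across default N=54 cohorts, LOO-predicted ln(a_pem) correlates
        positively with the fitted values (baseline burden carries real
        information about the drug effect despite per-patient fit noise)."""
        from pembropred import personalization
        from pembropred.cohort import CohortConfig, generate_cohort

        correlations = []
        for seed in (1, 2, 3):
            res = generate_cohort(CohortConfig(seed=seed))
            config = RunConfig(seed=seed)
            _, table, _ = run_fit_stage(res.records, config)
            cov = covariate_frame(res.records).loc[table.index]
            loo = personalization.loo_cross_validate(
                cov, table["ln_a_pem"], table["gamma_mel"])
            correlations.append(
                np.corrcoef(loo["ln_a_pem"], table["ln_a_pem"])[0, 1])
        assert np.median(correlations) > 0.0


class TestPredictStage:
    def test_prediction_outputs_well_formed(self, tmp_path, noise_free_cohort,
                                            fit_result):
        config, _, table, _ = fit_result
        pred, metrics = run_predict_stage(noise_free_cohort.records, table,
                                          config, truth=noise_free_cohort.truth,
                                          outdir=tmp_path)
        assert pred["pred_interval"].between(1, 4).all()
        assert pred["obs_interval"].between(1, 4).all()
        assert pred["outcome"].between(1, 6).all()
        assert "pred_vs_truth" in metrics
        back = pd.read_csv(tmp_path / "predictions.csv").set_index("patient_id")
        pd.testing.assert_frame_equal(back, pred, check_dtype=False)

    def test_oracle_parameters_reproduce_truth_intervals(self, noise_free_cohort,
                                                         fit_result):
        """With the true parameters injected, predicted intervals match the
        generator's ground truth (both derive from the same noise-free model)."""
        config, _, table, _ = fit_result
        pred, metrics = run_predict_stage(noise_free_cohort.records, table,
                                          config, truth=noise_free_cohort.truth,
                                          oracle=True)
        kappa = metrics["pred_vs_truth"]["kappa"]["kappa"]
        assert kappa == pytest.approx(1.0)

    def test_censored_before_first_assessment_uses_truncated_horizon(self):
        records = [
            make_record("s1", [0.0, 60.0], [50.0, 80.0], 60.0,
                        {"breslow": 2.0, "nodular": 0.0}),
            make_record("s2", [0.0, 90.0], [60.0, 60.0], 100.0,
                        {"breslow": 3.0, "nodular": 0.0}),
            make_record("s3", [0.0, 90.0], [70.0, 75.0], 100.0,
                        {"breslow": 1.0, "nodular": 1.0}),
            make_record("s4", [0.0, 90.0], [40.0, 30.0], 100.0,
                        {"breslow": 5.0, "nodular": 0.0}),
        ]
        config = RunConfig()
        _, table, _ = run_fit_stage(records, config)
        pred, _ = run_predict_stage(records, table, config)
        # the 60-day patient is assessed once, at its own follow-up end
        assert pred.at["s1", "pred_interval"] in (1, 4)


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=3, density=20.0, noise_sigma=0.05)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = RunConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("not_a_real_option: 1\n")
        with pytest.raises(ConfigError):
            RunConfig.from_yaml(path)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(Exception):
            RunConfig(a_pem_bounds=(100.0, 10.0))


class TestReadCohort:
    def test_missing_column_reported(self, tmp_path):
        (tmp_path / "patients.csv").write_text("patient_id\np1\n")
        (tmp_path / "scans.csv").write_text("patient_id,day,sod_mm\np1,0,50\n")
        with pytest.raises(ParseError):
            read_cohort(tmp_path / "patients.csv", tmp_path / "scans.csv")

    def test_row_number_in_error(self, tmp_path, noisy_cohort):
        write_cohort_csvs(noisy_cohort.records, tmp_path)
        scans = pd.read_csv(tmp_path / "scans.csv")
        scans = scans[scans["day"] > 0]          # drop all baselines
        scans.to_csv(tmp_path / "scans.csv", index=False)
        with pytest.raises(ParseError, match="row"):
            read_cohort(tmp_path / "patients.csv", tmp_path / "scans.csv")


class TestCli:
    def test_synth_fit_evaluate_chain(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "run"
        r = runner.invoke(main, ["synth", "--out", str(out), "--n", "6",
                                 "--seed", "3", "--noise", "0.0"])
        assert r.exit_code == 0, r.output
        assert (out / "patients.csv").exists() and (out / "truth.csv").exists()

        r = runner.invoke(main, ["fit", "--patients", str(out / "patients.csv"),
                                 "--scans", str(out / "scans.csv"),
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "fitted_params.csv").exists()
        assert json.loads((out / "fit_metrics.json").read_text())["n_fitted"] == 6

    def test_config_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("no_such_key: 1\n")
        runner = CliRunner()
        r = runner.invoke(main, ["pipeline", "--config", str(bad),
                                 "--out", str(tmp_path / "o")])
        assert r.exit_code == 2

    def test_parse_error_exit_code(self, tmp_path):
        (tmp_path / "patients.csv").write_text("patient_id\np1\n")
        (tmp_path / "scans.csv").write_text("patient_id,day,sod_mm\np1,0,50\n")
        runner = CliRunner()
        r = runner.invoke(main, ["fit", "--patients",
                                 str(tmp_path / "patients.csv"),
                                 "--scans", str(tmp_path / "scans.csv"),
                                 "--out", str(tmp_path / "o")])
        assert r.exit_code == 3

    def test_pipeline_writes_manifest_and_summary(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "pipe"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({"n_patients": 8, "seed": 5,
                                       "outdir": str(out)}))
        r = runner.invoke(main, ["pipeline", "--config", str(cfg)])
        assert r.exit_code == 0, r.output
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 5 and "config_sha256" in manifest
        summary = json.loads((out / "summary.json").read_text())
        assert {"fit", "train", "predict", "oracle"} <= set(summary)
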