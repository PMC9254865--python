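"""Configuration schema, Model/Results surface, pipeline and CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from psmcea import PartitionedSurvivalModel, load_and_validate
from psmcea.cli import main as cli_main
from psmcea.config import ModelConfig, dump_config
from psmcea.fixtures import clear_like_config
from psmcea.pipeline import run_pipeline, substream_seed

LENV_PEMB = "lenvatinib_pembrolizumab"
SUNITINIB = "sunitinib"


class TestConfigSchema:
    def test_fixture_validates_with_three_strategies(self):
        cfg = clear_like_config()
        assert len(cfg.strategies) == 3
        assert cfg.reference == SUNITINIB
        assert cfg.wtp_thresholds == (217_341.0, 652_023.0)

    def test_unknown_key_rejected(self):
        raw = clear_like_config().model_dump()
        raw["no_such_section"] = 1
        with pytest.raises(Exception) as err:
            ModelConfig.model_validate(raw)
        assert "no_such_section" in str(err.value)

    def test_negative_cost_error_names_field(self):
        raw = clear_like_config().model_dump()
        raw["shared"]["terminal_care_cost"] = -5.0
        with pytest.raises(Exception) as err:
            ModelConfig.model_validate(raw)
        assert "terminal_care_cost" in str(err.value)

    def test_missing_reference_rejected(self):
        raw = clear_like_config().model_dump()
        raw["strategies"][SUNITINIB]["reference"] = False
        with pytest.raises(Exception) as err:
            ModelConfig.model_validate(raw)
        assert "reference" in str(err.value)

    def test_round_trip_idempotent(self, tmp_path):
        cfg = clear_like_config()
        path = tmp_path / "model.yaml"
        dump_config(cfg, path)
        again = load_and_validate(path)
        assert again == cfg
        # and a second dump is byte-identical
        assert dump_config(again) == dump_config(cfg)

    def test_hazard_ratio_reference_must_resolve(self):
        raw = clear_like_config().model_dump()
        raw["strategies"][LENV_PEMB]["curves"]["pfs"]["reference"] = "ghost"
        with pytest.raises(Exception):
            ModelConfig.model_validate(raw)


class TestModelSurface:
    def test_summary_mentions_all_strategies(self, base_results):
        text = base_results.summary()
        for name in base_results.strategy_results:
            assert name in text
        assert "ICER".lower() in text.lower() or "icer" in text

    def test_results_frame_reference_first(self, base_results):
        df = base_results.results_frame()
        assert df.iloc[0]["strategy"] == SUNITINIB
        assert np.isnan(df.iloc[0]["icer"])
        assert df.shape[0] == 3

    def test_reference_life_years_anchor(self, base_results):
        """The fixture pins reference discounted LY to the published 2.83."""
        assert base_results.strategy_results[SUNITINIB].ly == pytest.approx(
            2.83, abs=1e-6
        )

    def test_horizon_extension_only_adds_outcomes(self, fixture_model):
        short = fixture_model.run(horizon_years=5.0)
        long = fixture_model.run(horizon_years=20.0)
        for name in short:
            assert long[name].qaly >= short[name].qaly
            assert long[name].ly >= short[name].ly
            assert long[name].cost >= short[name].cost

    def test_run_with_override_changes_only_target(self, fixture_model):
        base = fixture_model.run()
        up = fixture_model.run(overrides={"price_pembrolizumab_per_mg": 215.02})
        assert up[LENV_PEMB].cost > base[LENV_PEMB].cost
        assert up[SUNITINIB].cost == pytest.approx(base[SUNITINIB].cost, rel=1e-12)
        assert up[LENV_PEMB].qaly == pytest.approx(base[LENV_PEMB].qaly, rel=1e-12)


class TestPipeline:
    @pytest.fixture(scope="class")
    def pipeline_out(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("pipeline")
        cfg = clear_like_config()
        run_pipeline(cfg, seed=7, out_dir=out, psa_n_iter=150)
        return out

    def test_emits_expected_artifacts(self, pipeline_out):
        for name in (
            "results.json", "tornado.csv", "psa_samples.csv", "ceac.csv",
            "scenarios.json", "subgroups.json", "run.log", "config.yaml",
        ):
            assert (pipeline_out / name).exists(), name

    def test_results_json_has_three_strategies(self, pipeline_out):
        results = json.loads((pipeline_out / "results.json").read_text())
        assert len(results["strategies"]) == 3
        assert results["reference"] == SUNITINIB
        for entry in results["strategies"].values():
            bd = entry["cost_breakdown"]
            assert bd["total"] == pytest.approx(
                sum(v for k, v in bd.items() if k != "total"), rel=1e-9
            )

    def test_csv_artifacts_parse_back(self, pipeline_out):
        import pandas as pd

        for name in ("tornado.csv", "psa_samples.csv", "ceac.csv"):
            df = pd.read_csv(pipeline_out / name)
            assert not df.empty

    def test_same_seed_reproduces_psa_bytes(self, tmp_path):
        cfg = clear_like_config()
        run_pipeline(cfg, seed=3, out_dir=tmp_path / "a", psa_n_iter=50)
        run_pipeline(cfg, seed=3, out_dir=tmp_path / "b", psa_n_iter=50)
        assert (tmp_path / "a/psa_samples.csv").read_bytes() == (
            tmp_path / "b/psa_samples.csv"
        ).read_bytes()

    def test_substream_seeds_distinct_and_bounded(self):
        seeds = {substream_seed(1, s) for s in ("simulate", "psa")}
        assert len(seeds) == 2
        assert all(0 <= s < 2**31 for s in seeds)


class TestCLI:
    def test_example_config_round_trips(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "model.yaml"
        result = runner.invoke(cli_main, ["example-config", "--out", str(out)])
        assert result.exit_code == 0, result.output
        cfg = load_and_validate(out)
        assert cfg == clear_like_config()

    def test_run_prints_summary(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["run", "--config", "fixture"])
        assert result.exit_code == 0, result.output
        assert SUNITINIB in result.output
        assert "base case" in result.output

    def test_reconstruct_and_fit_commands(self, tmp_path):
        from psmcea.synthetic import (
            calibrate_weibull_from_median,
            emit_km_artifacts,
            simulate_arm_ipd,
        )

        pfs, _ = simulate_arm_ipd(
            calibrate_weibull_from_median(9.2, 1.2),
            calibrate_weibull_from_median(30.0, 1.0),
            150, 12, 36, seed=2,
        )
        curve, risk = emit_km_artifacts(pfs, np.arange(0.0, 37.0, 3.0))
        curve.to_csv(tmp_path / "curve.csv")
        risk.to_csv(tmp_path / "risk.csv")
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["reconstruct", "--curve", str(tmp_path / "curve.csv"),
             "--risk", str(tmp_path / "risk.csv"),
             "--out", str(tmp_path / "ipd.csv")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            ["fit", "--ipd", str(tmp_path / "ipd.csv"), "--criterion", "aic",
             "--out", str(tmp_path / "fits.csv")],
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        fits = pd.read_csv(tmp_path / "fits.csv")
        assert fits["selected"].sum() == 1
        assert set(fits.columns) >= {"family", "loglik", "aic", "bic", "converged"}
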