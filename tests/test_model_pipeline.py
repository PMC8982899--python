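import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from omu_synergy import io_formats as io
from omu_synergy.cli import main as cli_main
from omu_synergy.model import PipelineOptions, SynergyModel
from omu_synergy.pipeline import run_all
from omu_synergy.simulate import StudyConfig, generate_study


class TestModelFacade:
    def test_results_consistency(self, small_results):
        lm = small_results.linear_model
        assert lm.r_squared == pytest.approx(lm.pearson_r**2, abs=1e-12)
        assert small_results.rsquared == lm.r_squared
        assert len(small_results.ranking) == len(small_results.scores)

    def test_summary_mentions_key_quantities(self, small_results):
        text = small_results.summary()
        assert "OMU" in text and "Pearson" in text and "balance" in text

    def test_refit_is_deterministic(self, small_study):
        a = SynergyModel.from_study(small_study, options=PipelineOptions(seed=11)).fit()
        b = SynergyModel.from_study(small_study, options=PipelineOptions(seed=11)).fit()
        pd.testing.assert_frame_equal(a.ranking, b.ranking)
        assert a.linear_model.to_dict() == b.linear_model.to_dict()

    def test_missing_grmax_rejected(self, small_study):
        from omu_synergy.io_formats import GRTable

        partial = GRTable(records=dict(list(small_study.gr_table.records.items())[:-1]))
        with pytest.raises(ValueError, match="without a GRmax"):
            SynergyModel(small_study.expression, small_study.prior,
                         small_study.ppi, partial)

    def test_unknown_control_rejected(self, small_study):
        with pytest.raises(ValueError, match="control"):
            SynergyModel(small_study.expression, small_study.prior,
                         small_study.ppi, small_study.gr_table,
                         control_id="nope")

    def test_plots_return_axes(self, small_results):
        ax1 = small_results.plot_fit()
        ax2 = small_results.plot_dgis_distribution()
        assert ax1.get_xlabel() == "ILR balance"
        assert ax2.get_xlabel() == "DGIS"


SMALL_RUN = {
    "study": {"n_drugs": 8, "n_tfs": 12, "n_genes": 50, "n_planted_modules": 4},
    "options": {"seed": 3, "top_k": 10},
}


class TestRunAll:
    def test_manifest_lists_all_stages(self, tmp_path):
        manifest = run_all(SMALL_RUN, tmp_path / "out")
        stages = [s["stage"] for s in manifest["stages"]]
        assert stages == ["simulate", "fit", "networks", "modules", "omu_system",
                          "model", "ranking", "dose_response", "enrichment",
                          "summary"]
        assert (tmp_path / "out" / "manifest.json").exists()
        assert (tmp_path / "out" / "ranking.tsv").exists()

    def test_rerun_same_seed_identical_checksums(self, tmp_path):
        m1 = run_all(SMALL_RUN, tmp_path / "a")
        m2 = run_all(SMALL_RUN, tmp_path / "b")
        assert m1["artifacts"] == m2["artifacts"]

    def test_missing_input_aborts_with_stage(self, tmp_path):
        config = {"inputs": {"expression": str(tmp_path / "missing.tsv"),
                             "prior": "x", "ppi": "y", "gr": "z"}}
        with pytest.raises(FileNotFoundError):
            run_all(config, tmp_path / "out")
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["failed_stage"] == "inputs"


class TestCLI:
    def test_stagewise_workflow(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        study_yaml = tmp_path / "study.yaml"
        study_yaml.write_text(yaml.dump(
            {"n_drugs": 6, "n_tfs": 12, "n_genes": 40, "n_planted_modules": 4}
        ))
        r = runner.invoke(cli_main, ["simulate", "--config", str(study_yaml),
                                     "--seed", "2", "--out-dir", str(sim_dir)])
        assert r.exit_code == 0, r.output
        grn_dir = tmp_path / "grns"
        r = runner.invoke(cli_main, [
            "grn", "--expr", str(sim_dir / "expression.tsv"),
            "--prior", str(sim_dir / "prior.tsv"),
            "--ppi", str(sim_dir / "ppi.tsv"), "--out-dir", str(grn_dir),
        ])
        assert r.exit_code == 0, r.output
        assert (grn_dir / "grn_control.tsv").exists()

        module_files = []
        for cond in ["drug1", "drug2", "drug3", "drug4", "drug5", "drug6"]:
            out = tmp_path / f"modules_{cond}.json"
            r = runner.invoke(cli_main, [
                "diffnet", "--treated", str(grn_dir / f"grn_{cond}.tsv"),
                "--control", str(grn_dir / "grn_control.tsv"),
                "--seed", "2", "--out", str(out),
            ])
            assert r.exit_code == 0, r.output
            module_files.append(out)

        omu_json = tmp_path / "omu.json"
        vec_tsv = tmp_path / "vec.tsv"
        args = ["omu", "--gr", str(sim_dir / "gr.csv"), "--out", str(omu_json),
                "--vectors-out", str(vec_tsv)]
        for f in module_files:
            args += ["--modules", str(f)]
        r = runner.invoke(cli_main, args)
        assert r.exit_code == 0, r.output

        model_json = tmp_path / "model.json"
        r = runner.invoke(cli_main, [
            "fit", "--system", str(omu_json), "--vectors", str(vec_tsv),
            "--gr", str(sim_dir / "gr.csv"), "--out", str(model_json),
        ])
        assert r.exit_code == 0, r.output

        ranking = tmp_path / "ranking.tsv"
        r = runner.invoke(cli_main, [
            "score", "--system", str(omu_json), "--vectors", str(vec_tsv),
            "--model", str(model_json), "--gr", str(sim_dir / "gr.csv"),
            "--out", str(ranking),
        ])
        assert r.exit_code == 0, r.output
        table = io.read_ranking(ranking)
        assert len(table) == 15  # C(6, 2)
        assert list(table["dgis"]) == sorted(table["dgis"])

    def test_zip_command(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(cli_main, ["simulate", "--seed", "4", "--out-dir",
                                 str(sim_dir)])
        out = tmp_path / "synergy.tsv"
        r = runner.invoke(cli_main, ["zip", "--matrix",
                                     str(sim_dir / "dose_response.csv"),
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        scored = pd.read_csv(out, sep="\t")
        assert {"drug_1", "drug_2", "zip", "synergy"} <= set(scored.columns)

    def test_enrich_command(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "enrich", "--top-hits", "8", "--top-n", "30",
            "--rand-hits", "2", "--rand-n", "160",
            "--finite-population", "1596",
        ])
        assert r.exit_code == 0, r.output
        doc = json.loads(r.output)
        assert doc["m_hat"] == pytest.approx(10 / 190, abs=1e-6)
        assert doc["m_hat_finite"] == pytest.approx(83 / 1596, abs=1e-9)

    def test_gr_command(self, tmp_path):
        counts = tmp_path / "counts.csv"
        pd.DataFrame({
            "drug": ["d1"] * 3,
            "conc": [0.1, 1.0, 10.0],
            "count_t": [5800, 4500, 3000],
            "control_count_t": [6000] * 3,
            "initial_count": [3000] * 3,
        }).to_csv(counts, index=False)
        out = tmp_path / "gr.csv"
        r = CliRunner().invoke(cli_main, ["gr", "--counts", str(counts),
                                          "--out", str(out)])
        assert r.exit_code == 0, r.output
        table = io.read_gr_table(out)
        assert table["d1"] == pytest.approx(0.0, abs=1e-9)
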