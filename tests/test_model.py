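import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import nodulegrowth as ng
from nodulegrowth.cli import main as cli_main
from nodulegrowth.io import SchemaError, read_measurements
from nodulegrowth.pipeline import PipelineConfig, run_pipeline


def worked_examples_frame():
    """Three nodules built from published follow-up vignettes: interval and
    relative volume change fixed, baseline volume arbitrary (doubling time is
    scale invariant)."""
    rows = []
    for pid, ntype, dt, rel in [
        ("fig5a", "pSN", 540, 108.28),
        ("fig5e", "SN", 327, 139.31),
        ("fig6", "SN", 415, 302.75),
    ]:
        v0, vt = 1000.0, 1000.0 * (1 + rel / 100.0)
        for day, v in [(0, v0), (dt, vt)]:
            solid = v * 0.4 if ntype == "pSN" else v
            rows.append(
                {
                    "patient_id": pid, "day": day, "nodule_type": ntype,
                    "diameter_whole_mm": v ** (1 / 3),
                    "diameter_solid_mm": solid ** (1 / 3),
                    "volume_whole_mm3": v, "volume_solid_mm3": solid,
                    "attenuation_hu": -45.0,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def fitted():
    m, p, _ = ng.simulate_cohort(ng.SimulationConfig(n_patients=400, seed=21))
    return ng.NoduleCohortModel(m, p).fit()


class TestModelFit:
    def test_results_carry_every_stage(self, fitted):
        assert {"kinetics", "growers", "filter_report", "univariable"} <= set(
            vars(fitted)
        )
        assert fitted.n_growers <= fitted.n_included <= len(fitted.filter_report)
        assert fitted.logistic is not None
        assert set(fitted.roc) == {"vdt_t", "mdt_t"}

    def test_summary_prints_headline_numbers(self, fitted):
        text = fitted.summary()
        assert "ROC vdt_t" in text and "AUC" in text
        assert "growth analysis set" in text

    def test_t_categories_assigned_from_baseline_diameter(self, fitted):
        tab = fitted.table.dropna(subset=["t_category"])
        small = tab[tab.baseline_diameter_mm < 10]
        assert (small.t_category == "T1a").all()

    def test_record_conservation_through_filtering(self, fitted):
        rep = fitted.filter_report
        assert len(rep) == 400
        assert rep.included.sum() == fitted.n_included

    def test_plot_roc_writes_file(self, fitted, tmp_path):
        out = tmp_path / "roc.png"
        fitted.plot_roc(path=out)
        assert out.stat().st_size > 0


class TestSchemaAndErrors:
    def test_missing_column_named_in_error(self, tmp_path):
        m, p, _ = ng.simulate_cohort(ng.SimulationConfig(n_patients=10, seed=0))
        bad = m.drop(columns=["attenuation_hu"])
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="attenuation_hu"):
            read_measurements(path)

    def test_empty_cohort_raises(self):
        m, p, _ = ng.simulate_cohort(ng.SimulationConfig(n_patients=6, seed=0))
        cfg = ng.EligibilityConfig(min_follow_up_days=5000, max_follow_up_days=6000)
        with pytest.raises(RuntimeError, match="eligibility"):
            ng.NoduleCohortModel(m, p, eligibility=cfg).fit()


class TestWorkedExamples:
    def test_caption_vignettes_reproduce_printed_doubling_times(self, tmp_path):
        path = tmp_path / "meas.csv"
        worked_examples_frame().to_csv(path, index=False)
        runner = CliRunner()
        out = tmp_path / "kinetics.csv"
        result = runner.invoke(
            cli_main,
            ["compute-kinetics", "--measurements", str(path), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        kin = pd.read_csv(out).set_index("patient_id")
        for pid, expected in [("fig5a", 510), ("fig5e", 259), ("fig6", 207)]:
            assert abs(kin.loc[pid, "vdt_t"] - expected) <= 1.0


class TestPipelineDeterminism:
    def test_two_runs_are_byte_identical(self, tmp_path):
        manifests = []
        for name in ("r1", "r2"):
            cfg = PipelineConfig(
                out_dir=tmp_path / name, simulate=True,
                simulation=ng.SimulationConfig(n_patients=150), seed=7,
            )
            manifests.append(run_pipeline(cfg))
        assert {k: v["rows"] for k, v in manifests[0].items()} == {
            k: v["rows"] for k, v in manifests[1].items()
        }
        for name in manifests[0]:
            a = (tmp_path / "r1" / name).read_bytes()
            b = (tmp_path / "r2" / name).read_bytes()
            if name.endswith((".csv", ".txt")):
                assert a == b, name

    def test_manifest_counts_conserve_records(self, tmp_path):
        cfg = PipelineConfig(
            out_dir=tmp_path / "m", simulate=True,
            simulation=ng.SimulationConfig(n_patients=120), seed=3,
        )
        manifest = run_pipeline(cfg)
        assert manifest["measurements.csv"]["rows"] == 240
        assert manifest["patients.csv"]["rows"] == 120
        assert manifest["filter_report.csv"]["rows"] == 120
        summary = json.loads((tmp_path / "m" / "filter_summary.json").read_text())
        assert summary["included"] + sum(summary["excluded_by_reason"].values()) == 120


class TestCLI:
    def test_simulate_then_analyze_round_trip(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r = runner.invoke(
            cli_main, ["simulate", "--n", "150", "--seed", "5", "--out-dir", str(sim_dir)]
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            [
                "analyze",
                "--measurements", str(sim_dir / "measurements.csv"),
                "--patients", str(sim_dir / "patients.csv"),
                "--out-dir", str(tmp_path / "an"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "an" / "roc_summary.json").exists()
        assert (tmp_path / "an" / "manifest.json").exists()

    def test_validate_reports_violations(self, tmp_path):
        m, _, _ = ng.simulate_cohort(ng.SimulationConfig(n_patients=5, seed=2))
        m.loc[0, "volume_solid_mm3"] = m.loc[0, "volume_whole_mm3"] * 2
        path = tmp_path / "m.csv"
        m.to_csv(path, index=False)
        r = CliRunner().invoke(cli_main, ["validate", "--measurements", str(path)])
        assert r.exit_code == 1
        assert "volume_solid" in r.output
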