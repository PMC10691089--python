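"""End-to-end pipeline: (simulate |) validate -> filter -> kinetics -> stats.

Every stage writes its table under the output directory and the run closes
with a manifest JSON listing each artifact with its row count, so record
conservation across stages is auditable.  All randomness flows from the
single seed in the configuration; stages never read system entropy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .filters import EligibilityConfig
from .io import read_measurements, read_patients
from .model import NoduleCohortModel
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("nodulegrowth")


@dataclass
class PipelineConfig:
    out_dir: Union[str, Path] = "nodulegrowth_out"
    measurements_path: Optional[str] = None
    patients_path: Optional[str] = None
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    eligibility: Optional[EligibilityConfig] = field(default_factory=EligibilityConfig)
    filters_enabled: bool = True
    covariates: str = "reported"
    roc_direction: str = "lower-is-positive"
    seed: int = 0
    log_level: str = "INFO"


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest[path.name] = {"path": str(path), "rows": int(len(df))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the artifact manifest dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}

    if config.simulate:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        logger.info("simulating cohort: n=%d seed=%d", sim.n_patients, sim.seed)
        measurements, patients, truth = simulate_cohort(sim)
        _write(measurements, out / "measurements.csv", manifest)
        _write(patients, out / "patients.csv", manifest)
        _write(truth, out / "truth.csv", manifest)
    else:
        if not config.measurements_path or not config.patients_path:
            raise ValueError("measurements_path and patients_path required unless simulating")
        measurements = read_measurements(config.measurements_path)
        patients = read_patients(config.patients_path)

    eligibility = config.eligibility if config.filters_enabled else False
    if eligibility is not None and eligibility is not False:
        logger.info(
            "eligibility defaults in effect: follow-up strictly in (%d, %d) d, "
            "diameter <= %.0f mm, exclude_shrinking=%s",
            eligibility.min_follow_up_days,
            eligibility.max_follow_up_days,
            eligibility.max_diameter_mm,
            eligibility.exclude_shrinking,
        )
    model = NoduleCohortModel(measurements, patients, eligibility=eligibility)
    results = model.fit(
        covariates=config.covariates, roc_direction=config.roc_direction
    )

    _write(results.filter_report, out / "filter_report.csv", manifest)
    reason_counts = (
        results.filter_report.loc[results.filter_report.included == 0, "reason"]
        .value_counts()
        .to_dict()
    )
    filter_summary = {
        "total": int(len(results.filter_report)),
        "included": int(results.filter_report.included.sum()),
        "excluded_by_reason": {k: int(v) for k, v in reason_counts.items()},
    }
    (out / "filter_summary.json").write_text(json.dumps(filter_summary, indent=2))
    manifest["filter_summary.json"] = {
        "path": str(out / "filter_summary.json"),
        "rows": filter_summary["total"],
    }

    _write(results.kinetics, out / "kinetics.csv", manifest)
    _write(results.growers, out / "growth_analysis_set.csv", manifest)
    _write(results.summary_by_type, out / "summary_by_type.csv", manifest)
    _write(results.univariable, out / "univariable.csv", manifest)
    if results.logistic is not None:
        _write(results.logistic.summary(), out / "logistic.csv", manifest)
    roc_json = {}
    for name, r in results.roc.items():
        _write(r.curve, out / f"roc_curve_{name}.csv", manifest)
        roc_json[name] = {
            "auc": r.auc,
            "auc_ci": [r.auc_ci_low, r.auc_ci_high],
            "threshold_days": r.threshold,
            "sensitivity_pct": r.sensitivity,
            "specificity_pct": r.specificity,
            "direction": r.direction,
        }
    (out / "roc_summary.json").write_text(json.dumps(roc_json, indent=2))
    manifest["roc_summary.json"] = {"path": str(out / "roc_summary.json"),
                                    "rows": len(roc_json)}
    (out / "summary.txt").write_text(results.summary() + "\n")
    manifest["summary.txt"] = {"path": str(out / "summary.txt"), "rows": 1}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(manifest), out)
    return manifest
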