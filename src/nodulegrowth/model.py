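"""Model/Results surface tying the pipeline together.

``NoduleCohortModel`` is built from the two input tables (serial CT
measurements and per-patient clinical records); ``fit()`` runs validation,
eligibility filtering, per-nodule growth kinetics, and the cohort
statistical battery, returning a ``NoduleCohortResults`` object that
carries every intermediate table, the fitted metastasis model, and the ROC
summaries, with a ``summary()`` text report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as ngio
from .datatypes import OutOfScopeDiameterError, assign_t_category, validate_series
from .filters import EligibilityConfig, analysis_set_for_doubling_times, apply_eligibility
from .kinetics import compute_kinetics
from .stats import (
    LogisticFit,
    RocSummary,
    fit_logistic,
    roc_analysis,
    summarize_groups,
    univariable_screen,
)

__all__ = ["NoduleCohortModel", "NoduleCohortResults", "COVARIATE_PRESETS"]

logger = logging.getLogger("nodulegrowth")

#: named covariate sets for the metastasis logistic model.  "reported" is the
#: full multivariable list used in the clinical analysis this package
#: operationalises (note it mixes collinear growth measures deliberately);
#: "doubling_time" is a parsimonious alternative.
COVARIATE_PRESETS: dict[str, list[str]] = {
    "reported": [
        "baseline_diameter_mm",
        "solid_increase_mm",
        "volume_increase_mm3",
        "mass_increase_g",
        "vdt_t",
        "mdt_t",
    ],
    "doubling_time": ["baseline_diameter_mm", "vdt_t"],
}

EmptyCohortError = type("EmptyCohortError", (RuntimeError,), {
    "__doc__": "No records survived eligibility filtering."})


class NoduleCohortModel:
    """Growth-kinetics and metastasis-risk analysis of a follow-up cohort.

    Parameters
    ----------
    measurements : DataFrame
        Serial CT measurement table (see :mod:`nodulegrowth.io` schema).
    patients : DataFrame
        Per-patient clinical table.
    eligibility : EligibilityConfig, None, or False
        Cohort eligibility rules; ``False`` disables filtering entirely
        (useful for worked single-nodule examples), ``None`` uses defaults.
    """

    def __init__(
        self,
        measurements: pd.DataFrame,
        patients: pd.DataFrame,
        eligibility: Union[EligibilityConfig, None, bool] = None,
    ) -> None:
        ngio._require_columns(measurements, ngio.MEASUREMENT_COLUMNS, "measurement")
        ngio._require_columns(patients, ngio.PATIENT_COLUMNS, "patient")
        self.measurements = measurements
        self.patients = patients
        if eligibility is False:
            self.eligibility: Optional[EligibilityConfig] = None
        else:
            self.eligibility = eligibility or EligibilityConfig()

    @classmethod
    def from_csv(cls, measurements_path, patients_path, **kwargs) -> "NoduleCohortModel":
        return cls(
            ngio.read_measurements(measurements_path),
            ngio.read_patients(patients_path),
            **kwargs,
        )

    # ------------------------------------------------------------------

    def fit(
        self,
        covariates: Union[str, Sequence[str]] = "reported",
        roc_on: Sequence[str] = ("vdt_t", "mdt_t"),
        roc_direction: str = "lower-is-positive",
    ) -> "NoduleCohortResults":
        series_all = ngio.measurements_to_series(self.measurements)
        records = ngio.patients_to_records(self.patients)
        validation = {
            s.patient_id: v for s in series_all if (v := validate_series(s))
        }

        if self.eligibility is not None:
            included, filter_report = apply_eligibility(
                series_all, records, self.eligibility
            )
            logger.info(
                "eligibility: %d/%d included; exclusions: %s",
                len(included),
                len(series_all),
                filter_report.loc[filter_report.included == 0, "reason"]
                .value_counts()
                .to_dict(),
            )
        else:
            included = series_all
            filter_report = pd.DataFrame(
                {
                    "patient_id": [s.patient_id for s in series_all],
                    "included": 1,
                    "reason": "",
                }
            )
        if not included:
            raise EmptyCohortError("no records survived eligibility filtering")

        kin = ngio.kinetics_to_frame([compute_kinetics(s) for s in included])
        extra = pd.DataFrame([self._geometry_row(s) for s in included])
        kin = kin.merge(extra, on="patient_id")
        table = kin.merge(self.patients, on="patient_id", how="left")
        table["t_category"] = [
            _safe_t_category(d) for d in table["baseline_diameter_mm"]
        ]
        table["ln_positive"] = (table["ln_status"] == "N1/2").astype(int)
        growers = analysis_set_for_doubling_times(table)

        summary_by_type = summarize_groups(
            table,
            "nodule_type",
            continuous=[
                "baseline_diameter_mm",
                "baseline_volume_mm3",
                "baseline_mass_g",
                "diameter_increase_mm",
                "volume_increase_mm3",
                "mass_increase_g",
                "rel_diameter_change",
                "rel_volume_change",
                "rel_mass_change",
            ],
            categorical=["t_category", "ln_status"],
        )
        screen_vars = [
            "sex", "smoking_index", "nodule_type", "pathology", "t_category",
            "baseline_diameter_mm", "baseline_volume_mm3", "baseline_mass_g",
            "diameter_increase_mm", "volume_increase_mm3", "mass_increase_g",
            "rel_diameter_change", "rel_volume_change", "rel_mass_change",
        ]
        univariable = univariable_screen(table, "ln_positive", screen_vars)

        cov = COVARIATE_PRESETS[covariates] if isinstance(covariates, str) else list(covariates)
        logistic_table = growers.dropna(subset=[c for c in cov if c in growers])
        logistic = (
            fit_logistic(logistic_table, "ln_positive", cov)
            if len(logistic_table) and logistic_table["ln_positive"].nunique() == 2
            else None
        )

        roc: dict[str, RocSummary] = {}
        for score in roc_on:
            sub = growers.dropna(subset=[score])
            if len(sub) and sub["ln_positive"].nunique() == 2:
                roc[score] = roc_analysis(
                    sub[score], sub["ln_positive"], direction=roc_direction
                )

        return NoduleCohortResults(
            model=self,
            validation=validation,
            filter_report=filter_report,
            kinetics=kin,
            table=table,
            growers=growers,
            summary_by_type=summary_by_type,
            univariable=univariable,
            logistic=logistic,
            roc=roc,
        )

    @staticmethod
    def _geometry_row(series) -> dict:
        o0, ot = series.baseline, series.last
        return {
            "patient_id": series.patient_id,
            "baseline_diameter_mm": o0.diameter_whole,
            "baseline_volume_mm3": o0.volume_whole,
            "baseline_mass_g": o0.mass_whole,
            "diameter_increase_mm": ot.diameter_whole - o0.diameter_whole,
            "solid_increase_mm": ot.diameter_solid - o0.diameter_solid,
            "volume_increase_mm3": ot.volume_whole - o0.volume_whole,
            "mass_increase_g": ot.mass_whole - o0.mass_whole,
        }


def _safe_t_category(diameter: float) -> Optional[str]:
    try:
        return assign_t_category(diameter)
    except OutOfScopeDiameterError:
        return None


@dataclass
class NoduleCohortResults:
    """Fitted cohort analysis: every intermediate table plus the headline
    metastasis model and ROC summaries."""

    model: NoduleCohortModel
    validation: dict[str, list[str]]
    filter_report: pd.DataFrame
    kinetics: pd.DataFrame
    table: pd.DataFrame
    growers: pd.DataFrame
    summary_by_type: pd.DataFrame
    univariable: pd.DataFrame
    logistic: Optional[LogisticFit]
    roc: dict[str, RocSummary] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return len(self.kinetics)

    @property
    def n_growers(self) -> int:
        return len(self.growers)

    def mean_doubling_times(self) -> pd.DataFrame:
        """Mean VDT/MDT (whole nodule and solid component) by texture,
        over the growth analysis set."""
        return (
            self.growers.groupby("nodule_type")[["vdt_t", "mdt_t", "vdt_c", "mdt_c"]]
            .mean()
            .round(0)
        )

    def summary(self) -> str:
        lines = [
            "Nodule growth-kinetics cohort analysis",
            "=" * 48,
            f"records: {len(self.filter_report)}   included: {self.n_included}"
            f"   growth analysis set (>=25% volume): {self.n_growers}",
        ]
        excl = self.filter_report.loc[
            self.filter_report.included == 0, "reason"
        ].value_counts()
        if len(excl):
            lines.append(
                "exclusions: "
                + ", ".join(f"{k}={v}" for k, v in excl.items())
            )
        if self.n_growers:
            lines.append("")
            lines.append("mean doubling times (days) over growth set:")
            lines.append(self.mean_doubling_times().to_string())
        for score, r in self.roc.items():
            lines.append("")
            lines.append(
                f"ROC {score} vs LN metastasis ({r.direction}): "
                f"AUC {r.auc:.3f} (95% CI {r.auc_ci_low:.3f}-{r.auc_ci_high:.3f}), "
                f"threshold {r.threshold:.0f} d, "
                f"sensitivity {r.sensitivity:.1f}%, specificity {r.specificity:.1f}%"
            )
        if self.logistic is not None:
            lines.append("")
            lines.append("multivariable logistic model (odds ratios, Wald 95% CI):")
            tab = self.logistic.summary()
            with pd.option_context("display.width", 120):
                lines.append(tab.to_string(index=False))
            if not self.logistic.reliable:
                lines.append(
                    "  [warning] fit flagged unreliable "
                    "(non-convergence or separation)"
                )
        return "\n".join(lines)

    def plot_roc(self, scores: Optional[Sequence[str]] = None, path=None):
        """ROC curves for the fitted scores; returns the matplotlib axes."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for name in scores or self.roc:
            r = self.roc[name]
            curve = r.curve.sort_values("fpr")
            ax.plot(curve["fpr"], curve["tpr"], label=f"{name} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="reference (AUC 0.5)")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return ax
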