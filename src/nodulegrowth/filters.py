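"""Cohort eligibility and analysis-set rules applied to tabular records.

The study design restricts the cohort to resected adenocarcinomas <= 3 cm
with a preoperative follow-up interval strictly between 3 and 12 months and
without volume reduction over follow-up; separately, doubling times are
computed only on the subset of nodules with >= 25% relative volume growth.
Each excluded record carries exactly one primary exclusion reason so that a
flowchart-style accounting of the cohort remains possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .datatypes import PATHOLOGY_CLASSES, NoduleSeries, PatientRecord, validate_series

__all__ = [
    "EligibilityConfig",
    "apply_eligibility",
    "analysis_set_for_doubling_times",
    "REASON_INCLUDED",
    "REASON_DIAMETER",
    "REASON_PATHOLOGY",
    "REASON_FOLLOW_UP",
    "REASON_SHRINKAGE",
    "REASON_MALFORMED",
]

REASON_INCLUDED = ""
REASON_MALFORMED = "malformed"
REASON_DIAMETER = "diameter"
REASON_PATHOLOGY = "pathology"
REASON_FOLLOW_UP = "follow_up_window"
REASON_SHRINKAGE = "shrinkage"


@dataclass(frozen=True)
class EligibilityConfig:
    """Eligibility window and rules; defaults encode the study design.

    The follow-up bounds are exclusive (an interval of exactly
    ``min_follow_up_days`` or ``max_follow_up_days`` is excluded), mapping
    "3 months" and "12 months" to 90 and 365 days.  Both are configurable
    because worked single-nodule examples legitimately bypass the window.
    """

    min_follow_up_days: int = 90
    max_follow_up_days: int = 365
    max_diameter_mm: float = 30.0
    exclude_shrinking: bool = True
    require_adenocarcinoma: bool = True

    def __post_init__(self) -> None:
        if not self.min_follow_up_days < self.max_follow_up_days:
            raise ValueError("min_follow_up_days must be < max_follow_up_days")
        if not self.max_diameter_mm > 0:
            raise ValueError("max_diameter_mm must be > 0")


def _exclusion_reason(
    series: NoduleSeries,
    patient: Optional[PatientRecord],
    config: EligibilityConfig,
) -> str:
    """Primary exclusion reason, evaluated in fixed precedence order."""
    if patient is None or validate_series(series):
        return REASON_MALFORMED
    if series.baseline.diameter_whole > config.max_diameter_mm:
        return REASON_DIAMETER
    if config.require_adenocarcinoma and patient.pathology not in PATHOLOGY_CLASSES:
        return REASON_PATHOLOGY
    if not (
        config.min_follow_up_days < series.follow_up_days < config.max_follow_up_days
    ):
        return REASON_FOLLOW_UP
    if config.exclude_shrinking and series.last.volume_whole < series.baseline.volume_whole:
        return REASON_SHRINKAGE
    return REASON_INCLUDED


def apply_eligibility(
    series_list: Iterable[NoduleSeries],
    patients: Mapping[str, PatientRecord],
    config: EligibilityConfig | None = None,
) -> tuple[list[NoduleSeries], pd.DataFrame]:
    """Split records into the eligible cohort and an exclusion report.

    Returns ``(included_series, report)`` where the report has one row per
    input series with columns ``patient_id``, ``included`` (0/1) and
    ``reason`` (empty for included records).  Counts are conserved: every
    input record appears exactly once.
    """
    config = config or EligibilityConfig()
    included: list[NoduleSeries] = []
    rows = []
    for series in series_list:
        reason = _exclusion_reason(series, patients.get(series.patient_id), config)
        if reason == REASON_INCLUDED:
            included.append(series)
        rows.append(
            {
                "patient_id": series.patient_id,
                "included": int(reason == REASON_INCLUDED),
                "reason": reason,
            }
        )
    report = pd.DataFrame(rows, columns=["patient_id", "included", "reason"])
    return included, report


def analysis_set_for_doubling_times(kinetics: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the doubling-time statistics: relative volume change >= 25%."""
    return kinetics.loc[kinetics["grew_volume"].astype(bool)].copy()
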