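"""Tabular interchange formats (CSV, UTF-8, comma-separated, header required).

Two input tables drive the pipeline:

* measurement table — one row per CT examination per nodule, columns
  ``patient_id, day, nodule_type, diameter_whole_mm, diameter_solid_mm,
  volume_whole_mm3, volume_solid_mm3, attenuation_hu``; for solid nodules
  missing solid-component fields are auto-filled from the whole-nodule
  fields,
* patient table — one row per patient with demographics, surgery, lobe,
  pathology (AIS/MIA/IA) and nodal status (N0 vs N1/2).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .datatypes import (
    SOLID,
    KineticsResult,
    NoduleObservation,
    NoduleSeries,
    PatientRecord,
)

__all__ = [
    "SchemaError",
    "MEASUREMENT_COLUMNS",
    "PATIENT_COLUMNS",
    "read_measurements",
    "measurements_to_series",
    "series_to_frame",
    "read_patients",
    "patients_to_records",
    "kinetics_to_frame",
]

PathLike = Union[str, Path]

MEASUREMENT_COLUMNS = [
    "patient_id",
    "day",
    "nodule_type",
    "diameter_whole_mm",
    "diameter_solid_mm",
    "volume_whole_mm3",
    "volume_solid_mm3",
    "attenuation_hu",
]

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "family_history",
    "malignancy_history",
    "smoking_index",
    "surgery",
    "location",
    "pathology",
    "ln_status",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_measurements(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, "measurement")
    return df


def read_patients(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PATIENT_COLUMNS, "patient")
    return df


def measurements_to_series(df: pd.DataFrame) -> list[NoduleSeries]:
    """Group measurement rows into per-nodule series, ordered by day.

    Solid-nodule rows with missing solid-component fields are filled from the
    whole-nodule fields (consolidation/tumour ratio 1 by definition).
    """
    _require_columns(df, MEASUREMENT_COLUMNS, "measurement")
    out: list[NoduleSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        ntype = str(grp["nodule_type"].iloc[0])
        obs = []
        for row in grp.itertuples(index=False):
            d_solid = row.diameter_solid_mm
            v_solid = row.volume_solid_mm3
            if ntype == SOLID:
                if d_solid is None or (isinstance(d_solid, float) and math.isnan(d_solid)):
                    d_solid = row.diameter_whole_mm
                if v_solid is None or (isinstance(v_solid, float) and math.isnan(v_solid)):
                    v_solid = row.volume_whole_mm3
            obs.append(
                NoduleObservation(
                    day=int(row.day),
                    diameter_whole=float(row.diameter_whole_mm),
                    diameter_solid=float(d_solid),
                    volume_whole=float(row.volume_whole_mm3),
                    volume_solid=float(v_solid),
                    attenuation_mean=float(row.attenuation_hu),
                )
            )
        out.append(NoduleSeries(str(pid), ntype, obs))
    return out


def series_to_frame(series_list: Iterable[NoduleSeries]) -> pd.DataFrame:
    """Inverse of :func:`measurements_to_series` (round-trip safe)."""
    rows = []
    for s in series_list:
        for o in s.observations:
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "day": o.day,
                    "nodule_type": s.nodule_type,
                    "diameter_whole_mm": o.diameter_whole,
                    "diameter_solid_mm": o.diameter_solid,
                    "volume_whole_mm3": o.volume_whole,
                    "volume_solid_mm3": o.volume_solid,
                    "attenuation_hu": o.attenuation_mean,
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def patients_to_records(df: pd.DataFrame) -> dict[str, PatientRecord]:
    _require_columns(df, PATIENT_COLUMNS, "patient")
    records: dict[str, PatientRecord] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        records[pid] = PatientRecord(
            patient_id=pid,
            sex=str(row.sex),
            age=float(row.age),
            family_history=bool(row.family_history),
            malignancy_history=bool(row.malignancy_history),
            smoking_index=str(row.smoking_index),
            surgery=str(row.surgery),
            location=str(row.location),
            pathology=str(row.pathology),
            ln_status=str(row.ln_status),
            t_category=getattr(row, "t_category", None),
        )
    return records


def kinetics_to_frame(results: Iterable[KineticsResult]) -> pd.DataFrame:
    """Kinetics results as a table; undefined doubling times become NaN
    (written as empty cells in CSV)."""
    rows = [dataclasses.asdict(r) for r in results]
    cols = [f.name for f in dataclasses.fields(KineticsResult)]
    return pd.DataFrame(rows, columns=cols)
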