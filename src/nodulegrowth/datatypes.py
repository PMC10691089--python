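"""Domain data model for serial-CT nodule follow-up.

Unit conventions used throughout the package:

* time — integer day offsets from the first examination (day 0); calendar
  dates are converted at the I/O boundary,
* diameters — millimetres (mean of the longest diameters),
* volumes — cubic millimetres,
* attenuation — Hounsfield units (HU), averaged over three levels,
* physical density — mg/mL, obtained as ``HU + 1000``,
* mass — grams, ``volume_mm3 * density_mg_per_mL * 1e-6``.

Nodule texture classes: ``SN`` (solid nodule, the entire lesion is solid,
consolidation/tumour ratio 1) and ``pSN`` (part-solid nodule, a solid core
within ground-glass opacity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "SOLID",
    "PART_SOLID",
    "NoduleObservation",
    "NoduleSeries",
    "PatientRecord",
    "KineticsResult",
    "OutOfScopeDiameterError",
    "validate_series",
    "assign_t_category",
]

SOLID = "SN"
PART_SOLID = "pSN"

PATHOLOGY_CLASSES = ("AIS", "MIA", "IA")
LN_CLASSES = ("N0", "N1/2")

# relative tolerance for cross-checking stored derived fields (density, mass)
_DERIVED_RTOL = 1e-9


class OutOfScopeDiameterError(ValueError):
    """Baseline diameter outside the (0, 30] mm T1 size range."""


@dataclass(frozen=True)
class NoduleObservation:
    """One CT time point for one nodule.

    ``density`` and the masses are derived on construction when not given:
    density = attenuation + 1000 (mg/mL), mass = volume x density x 1e-6 (g).
    The solid-component mass uses ``attenuation_solid`` when recorded and
    falls back to the whole-nodule attenuation otherwise.
    """

    day: int
    diameter_whole: float
    diameter_solid: float
    volume_whole: float
    volume_solid: float
    attenuation_mean: float
    attenuation_solid: Optional[float] = None
    density: float = field(default=None)  # type: ignore[assignment]
    mass_whole: float = field(default=None)  # type: ignore[assignment]
    mass_solid: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.density is None:
            object.__setattr__(self, "density", self.attenuation_mean + 1000.0)
        if self.mass_whole is None:
            object.__setattr__(
                self, "mass_whole", self.volume_whole * self.density * 1e-6
            )
        if self.mass_solid is None and self.volume_solid > 0:
            att = (
                self.attenuation_solid
                if self.attenuation_solid is not None
                else self.attenuation_mean
            )
            object.__setattr__(
                self, "mass_solid", self.volume_solid * (att + 1000.0) * 1e-6
            )


@dataclass(frozen=True)
class NoduleSeries:
    """Ordered observations of one nodule; the unit kinetics are computed on."""

    patient_id: str
    nodule_type: str  # SOLID or PART_SOLID
    observations: tuple[NoduleObservation, ...]

    def __init__(
        self,
        patient_id: str,
        nodule_type: str,
        observations: Sequence[NoduleObservation],
    ) -> None:
        object.__setattr__(self, "patient_id", str(patient_id))
        object.__setattr__(self, "nodule_type", nodule_type)
        object.__setattr__(self, "observations", tuple(observations))

    @property
    def follow_up_days(self) -> int:
        return int(self.observations[-1].day - self.observations[0].day)

    @property
    def baseline(self) -> NoduleObservation:
        return self.observations[0]

    @property
    def last(self) -> NoduleObservation:
        return self.observations[-1]


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient clinical record accompanying one followed nodule."""

    patient_id: str
    sex: str  # female | male
    age: float  # years
    family_history: bool
    malignancy_history: bool
    smoking_index: str  # nonsmoker | <400 | >=400
    surgery: str  # lobectomy | segmentectomy
    location: str  # one of five lobes
    pathology: str  # AIS | MIA | IA
    ln_status: str  # N0 | N1/2
    t_category: Optional[str] = None  # derived from baseline whole diameter


@dataclass(frozen=True)
class KineticsResult:
    """Per-nodule growth metrics over the follow-up interval.

    Doubling times are in days and ``None`` whenever undefined: a whole-nodule
    doubling time requires >=25% relative volume growth and a positive change
    in the respective quantity; solid-component doubling times use the same
    rule on the solid-component volume.  For a solid nodule the component
    metrics coincide with the whole-nodule metrics.
    """

    patient_id: str
    nodule_type: str
    delta_t: int
    rel_diameter_change: float
    rel_volume_change: float
    rel_mass_change: float
    rel_solid_diameter_change: float
    rel_solid_volume_change: float
    rel_solid_mass_change: float
    grew_volume: bool
    grew_diameter: bool
    grew_mass: bool
    vdt_t: Optional[float]
    mdt_t: Optional[float]
    vdt_c: Optional[float]
    mdt_c: Optional[float]
    ct_ratio: float


def assign_t_category(baseline_diameter: float) -> str:
    """T-size category within clinical stage IA from baseline diameter (mm).

    T1a < 10 mm <= T1b < 20 mm <= T1c <= 30 mm.
    """
    if not baseline_diameter > 0 or baseline_diameter > 30:
        raise OutOfScopeDiameterError(
            f"baseline diameter {baseline_diameter!r} mm outside (0, 30] mm"
        )
    if baseline_diameter < 10:
        return "T1a"
    if baseline_diameter < 20:
        return "T1b"
    return "T1c"


def validate_series(series: NoduleSeries) -> list[str]:
    """Check every type invariant; return violation descriptions (empty = valid).

    Validation reports rather than raising so that malformed records can be
    accounted for as an explicit exclusion reason downstream.
    """
    v: list[str] = []
    obs = series.observations
    if series.nodule_type not in (SOLID, PART_SOLID):
        v.append(f"nodule_type: {series.nodule_type!r} is not one of SN/pSN")
    if len(obs) < 2:
        v.append(f"observations: need >=2 time points, got {len(obs)}")
    days = [o.day for o in obs]
    if any(b <= a for a, b in zip(days, days[1:])):
        v.append(f"day: values not strictly increasing ({days})")
    if obs and obs[0].day < 0:
        v.append(f"day: first observation at negative day {obs[0].day}")
    for i, o in enumerate(obs):
        tag = f"observation {i} (day {o.day})"
        if not o.diameter_whole > 0:
            v.append(f"diameter_whole: must be > 0 at {tag}")
        if not o.volume_whole > 0:
            v.append(f"volume_whole: must be > 0 at {tag}")
        if o.diameter_solid > o.diameter_whole:
            v.append(f"diameter_solid: exceeds diameter_whole at {tag}")
        if o.volume_solid > o.volume_whole:
            v.append(f"volume_solid: exceeds volume_whole at {tag}")
        if not o.density > 0:
            v.append(f"density: non-positive ({o.density} mg/mL) at {tag}")
        if abs(o.density - (o.attenuation_mean + 1000.0)) > _DERIVED_RTOL * max(
            1.0, abs(o.density)
        ):
            v.append(f"density: inconsistent with attenuation_mean + 1000 at {tag}")
        expected_mass = o.volume_whole * o.density * 1e-6
        if abs(o.mass_whole - expected_mass) > _DERIVED_RTOL * max(
            1.0, abs(expected_mass)
        ):
            v.append(f"mass_whole: inconsistent with volume x density at {tag}")
        if series.nodule_type == SOLID:
            if o.diameter_solid != o.diameter_whole or o.volume_solid != o.volume_whole:
                v.append(
                    f"nodule_type: SN requires solid component == whole nodule at {tag}"
                )
    if (
        series.nodule_type == PART_SOLID
        and obs
        and not obs[0].diameter_solid < obs[0].diameter_whole
    ):
        v.append("diameter_solid: pSN requires solid diameter < whole at baseline")
    return v
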