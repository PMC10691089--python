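"""Growth-kinetics formulas for serial CT nodule measurements.

A two-point exponential growth model underlies everything here: if a lesion
grows exponentially, the time for its volume to double is recovered from two
measurements by the modified Schwartz formula

    VDT = ln(2) * dT / ln(Vt / V0)

with V0 the initial and Vt the follow-up volume and dT the interval in days.
The same formula applied to nodule mass (volume times physical density,
density = CT attenuation in HU + 1000 mg/mL) gives the mass doubling time
(MDT).  Doubling times are only meaningful for growing lesions; by
convention they are computed only for nodules whose volume increased by at
least 25% over follow-up, and suffix "t" denotes the whole nodule while "c"
denotes the solid component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .datatypes import SOLID, KineticsResult, NoduleSeries

__all__ = [
    "GrowthPair",
    "NoGrowthError",
    "NonphysicalDensityError",
    "GROWTH_THRESHOLD_PCT",
    "hu_to_density",
    "nodule_mass",
    "relative_change",
    "doubling_time",
    "compute_kinetics",
]

#: minimum relative volume change (%) for a nodule to count as growing and
#: enter the doubling-time statistics
GROWTH_THRESHOLD_PCT = 25.0


class NoGrowthError(ValueError):
    """Doubling time requested for a non-growing lesion (xt <= x0)."""


class NonphysicalDensityError(ValueError):
    """Attenuation at or below -1000 HU implies non-positive density."""


@dataclass(frozen=True)
class GrowthPair:
    """Baseline/follow-up value pair (any single unit) over ``delta_t`` days."""

    x0: float
    xt: float
    delta_t: float

    def __post_init__(self) -> None:
        if not self.x0 > 0:
            raise ValueError(f"baseline value must be > 0, got {self.x0}")
        if not self.delta_t > 0:
            raise ValueError(f"delta_t must be > 0, got {self.delta_t}")


def hu_to_density(attenuation: float) -> float:
    """Physical density (mg/mL) from mean CT attenuation (HU): HU + 1000."""
    if attenuation <= -1000:
        raise NonphysicalDensityError(
            f"attenuation {attenuation} HU implies density <= 0 mg/mL"
        )
    return attenuation + 1000.0


def nodule_mass(volume: float, density: float) -> float:
    """Nodule mass in grams from volume (mm^3) and density (mg/mL)."""
    if not volume > 0 or not density > 0:
        raise ValueError(f"volume and density must be > 0, got {volume}, {density}")
    return volume * density * 1e-6


def relative_change(pair: GrowthPair) -> float:
    """Signed relative change (xt - x0)/x0 in percent; negative = shrinkage."""
    return (pair.xt - pair.x0) / pair.x0 * 100.0


def doubling_time(pair: GrowthPair) -> float:
    """Doubling time in days by the modified Schwartz formula.

    ln(2) * delta_t / ln(xt/x0), defined only for growing lesions (xt > x0).
    Applies identically to volumes (VDT) and masses (MDT).  Full precision is
    returned; round to whole days only at the presentation layer.
    """
    if pair.xt <= pair.x0:
        raise NoGrowthError(
            f"doubling time undefined for non-growing lesion "
            f"(x0={pair.x0}, xt={pair.xt})"
        )
    return math.log(2.0) * pair.delta_t / math.log(pair.xt / pair.x0)


def _dt_if_grown(x0: float, xt: Optional[float], delta_t: float) -> Optional[float]:
    if xt is None or xt <= x0 or x0 <= 0:
        return None
    return doubling_time(GrowthPair(x0, xt, delta_t))


def compute_kinetics(
    series: NoduleSeries, *, pairing: str = "first_last"
) -> KineticsResult | list[KineticsResult]:
    """Growth metrics for one nodule series.

    By default the first and last observations form the (baseline, follow-up)
    pair; ``pairing="consecutive"`` instead returns one result per successive
    pair of visits.  Whole-nodule doubling times are computed only when the
    relative volume change is >= 25% (and the respective change positive);
    solid-component doubling times use the same threshold on the
    solid-component volume.  For a solid nodule the component metrics equal
    the whole-nodule metrics by construction.
    """
    if pairing == "consecutive":
        return [
            _kinetics_for_pair(series, a, b)
            for a, b in zip(series.observations, series.observations[1:])
        ]
    if pairing != "first_last":
        raise ValueError(f"unknown pairing {pairing!r}")
    return _kinetics_for_pair(series, series.observations[0], series.observations[-1])


def _kinetics_for_pair(series, o0, ot) -> KineticsResult:
    dt = float(ot.day - o0.day)

    def rel(x0, xt):
        if x0 is None or xt is None or x0 <= 0:
            return math.nan
        return relative_change(GrowthPair(x0, xt, dt))

    rel_d = rel(o0.diameter_whole, ot.diameter_whole)
    rel_v = rel(o0.volume_whole, ot.volume_whole)
    rel_m = rel(o0.mass_whole, ot.mass_whole)
    if series.nodule_type == SOLID:
        rel_dc, rel_vc, rel_mc = rel_d, rel_v, rel_m
    else:
        rel_dc = rel(o0.diameter_solid, ot.diameter_solid)
        rel_vc = rel(o0.volume_solid, ot.volume_solid)
        rel_mc = rel(o0.mass_solid, ot.mass_solid)

    grew_volume = rel_v >= GROWTH_THRESHOLD_PCT
    grew_diameter = rel_d >= GROWTH_THRESHOLD_PCT
    grew_mass = rel_m >= GROWTH_THRESHOLD_PCT

    vdt_t = _dt_if_grown(o0.volume_whole, ot.volume_whole, dt) if grew_volume else None
    mdt_t = _dt_if_grown(o0.mass_whole, ot.mass_whole, dt) if grew_volume else None
    if series.nodule_type == SOLID:
        vdt_c, mdt_c = vdt_t, mdt_t
    else:
        grew_solid = not math.isnan(rel_vc) and rel_vc >= GROWTH_THRESHOLD_PCT
        vdt_c = _dt_if_grown(o0.volume_solid, ot.volume_solid, dt) if grew_solid else None
        mdt_c = (
            _dt_if_grown(o0.mass_solid or 0.0, ot.mass_solid, dt) if grew_solid else None
        )

    return KineticsResult(
        patient_id=series.patient_id,
        nodule_type=series.nodule_type,
        delta_t=int(dt),
        rel_diameter_change=rel_d,
        rel_volume_change=rel_v,
        rel_mass_change=rel_m,
        rel_solid_diameter_change=rel_dc,
        rel_solid_volume_change=rel_vc,
        rel_solid_mass_change=rel_mc,
        grew_volume=grew_volume,
        grew_diameter=grew_diameter,
        grew_mass=grew_mass,
        vdt_t=vdt_t,
        mdt_t=mdt_t,
        vdt_c=vdt_c,
        mdt_c=mdt_c,
        ct_ratio=o0.diameter_solid / o0.diameter_whole,
    )
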