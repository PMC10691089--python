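import pytest

from nodulegrowth.datatypes import NoduleObservation, NoduleSeries


def make_obs(day, volume, attenuation=0.0, *, diameter=None, solid_volume=None,
             solid_diameter=None):
    """Observation helper: defaults to a fully solid geometry."""
    diameter = diameter if diameter is not None else volume ** (1 / 3)
    solid_volume = solid_volume if solid_volume is not None else volume
    solid_diameter = solid_diameter if solid_diameter is not None else diameter
    return NoduleObservation(
        day=day,
        diameter_whole=diameter,
        diameter_solid=solid_diameter,
        volume_whole=volume,
        volume_solid=solid_volume,
        attenuation_mean=attenuation,
    )


def make_solid_series(v0, vt, dt, att0=0.0, att_t=0.0, patient_id="S1"):
    return NoduleSeries(
        patient_id, "SN", [make_obs(0, v0, att0), make_obs(dt, vt, att_t)]
    )


@pytest.fixture
def solid_doubling_series():
    """Solid nodule exactly doubling its volume in 360 days, constant density."""
    return make_solid_series(1000.0, 2000.0, 360)
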