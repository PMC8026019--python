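import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metpbpk as mp
from metpbpk.model_core import (
    Compartment,
    CompartmentKind,
    DoseEvent,
    RateLaw,
    flow_exchange_rate,
    linear_transport_rate,
    michaelis_menten_rate,
)

pos = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False,
                allow_infinity=False)


def test_unit_conversions_roundtrip():
    assert mp.mg_to_nmol(129.16e-6) == pytest.approx(1.0)
    assert mp.nmol_to_mg(mp.mg_to_nmol(3.7)) == pytest.approx(3.7)


def test_hydrochloride_conversion():
    # 1000 mg of the salt contains 778.4 mg of free base
    assert mp.hydrochloride_to_base_mg(1000.0) == pytest.approx(778.4)


@settings(max_examples=50, deadline=None)
@given(q=pos, c=pos, ktp=pos)
def test_flow_exchange_vanishes_at_equilibrium(q, c, ktp):
    # net tissue exchange is zero exactly when C_tissue = Ktp * C_plasma
    assert flow_exchange_rate(q, c, ktp * c, ktp) == pytest.approx(0.0, abs=1e-6 * q * c)


@settings(max_examples=50, deadline=None)
@given(q=pos, cs=pos, ct=pos, ktp=pos)
def test_flow_exchange_sign(q, cs, ct, ktp):
    rate = flow_exchange_rate(q, cs, ct, ktp)
    assert (rate > 0) == (cs > ct / ktp) or rate == 0


@settings(max_examples=50, deadline=None)
@given(vmax=pos, km=pos, s=pos)
def test_michaelis_menten_bounded_and_monotone(vmax, km, s):
    r = michaelis_menten_rate(vmax, km, s)
    assert 0 <= r < vmax
    assert r <= michaelis_menten_rate(vmax, km, 2 * s)


def test_michaelis_menten_half_saturation():
    assert michaelis_menten_rate(10.0, 3.0, 3.0) == pytest.approx(5.0)


def test_linear_transport_proportional():
    assert linear_transport_rate(2.0, 7.0) == pytest.approx(14.0)


@settings(max_examples=50, deadline=None)
@given(gfr=pos, active=pos)
def test_renal_clearance_additive(gfr, active):
    total = mp.renal_clearance_total(gfr, active)
    assert total == pytest.approx(gfr + active)
    assert total >= gfr


def test_dose_event_nmol_conversion():
    base = DoseEvent(0.0, 1.0, mp.Route.PO, mp.DoseForm.base)
    salt = DoseEvent(0.0, 1.0, mp.Route.PO, mp.DoseForm.hydrochloride)
    assert base.amount_nmol == pytest.approx(mp.mg_to_nmol(1.0))
    assert salt.amount_nmol == pytest.approx(mp.mg_to_nmol(0.7784))


def test_dose_schedule_repeated():
    sched = mp.DoseSchedule.repeated(500.0, 8, 12.0)
    assert len(sched.events) == 8
    assert sched.last_time == pytest.approx(84.0)
    assert sched.total_nmol == pytest.approx(8 * mp.mg_to_nmol(500 * 0.7784))


def test_negative_dose_rejected():
    with pytest.raises(mp.InvalidParameterError):
        DoseEvent(0.0, -1.0)


def test_decreasing_dose_times_rejected():
    with pytest.raises(mp.InvalidParameterError):
        mp.DoseSchedule((DoseEvent(2.0, 1.0), DoseEvent(1.0, 1.0)))


def test_compartment_requires_positive_volume():
    with pytest.raises(mp.InvalidParameterError):
        Compartment("x", 0.0, CompartmentKind.tissue_well_stirred, ktp=1.0)


def test_rate_law_requires_parameters():
    with pytest.raises(mp.InvalidParameterError):
        RateLaw("r", mp.RateForm.michaelis_menten, "a", "b", {"Vmax": 1.0})


def test_flow_balance_validation(mouse_model):
    mouse_model.validate_flow_balance()  # reference model is balanced


def test_model_accessors(mouse_model):
    assert mouse_model.n == 20
    assert mouse_model.volume("venous_plasma") > 0
    assert mouse_model.compartment("liver").ktp == pytest.approx(5.5)
    with pytest.raises(KeyError):
        mouse_model.index("no_such_compartment")
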