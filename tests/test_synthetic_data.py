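import numpy as np
import pandas as pd
import pytest

import metpbpk as mp
from metpbpk.synthetic_data import (
    HUMAN_URINE_TIMES,
    MOUSE_TISSUE_CURVES,
    SamplingScheme,
)


def test_noise_model_statistics():
    rng = np.random.default_rng(0)
    noise = mp.NoiseModel(cv=0.2)
    true = np.full(200_000, 10.0)
    obs = noise.apply(true, rng)
    assert obs.mean() == pytest.approx(10.0, rel=0.01)
    assert obs.std() / obs.mean() == pytest.approx(0.2, rel=0.05)
    assert (obs > 0).all()


def test_zero_cv_is_noiseless():
    rng = np.random.default_rng(0)
    v = np.array([1.0, 2.0])
    np.testing.assert_array_equal(mp.NoiseModel(0.0).apply(v, rng), v)


def test_scheme_times_must_increase():
    with pytest.raises(ValueError):
        SamplingScheme({"venous_plasma": (2.0, 1.0)})
    with pytest.raises(ValueError):
        SamplingScheme({"venous_plasma": (0.0, 1.0)})


def test_noiseless_dataset_matches_simulation(mouse_model):
    sched, scheme = mp.preset_wilcock_po()
    data = mp.generate_dataset(mouse_model, sched, scheme, noise=None, seed=0)
    res = mp.simulate(mouse_model, sched, 24.0)
    row = data[(data["curve"] == "liver") & (data["time_h"] == 4.0)]
    expected = np.interp(4.0, res.time, res.concentration("liver"))
    assert row["value"].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_same_seed_same_dataset(mouse_model):
    sched, scheme = mp.preset_wilcock_po()
    noise = mp.NoiseModel(0.1)
    d1 = mp.generate_dataset(mouse_model, sched, scheme, noise=noise, seed=5)
    d2 = mp.generate_dataset(mouse_model, sched, scheme, noise=noise, seed=5)
    pd.testing.assert_frame_equal(d1, d2)
    d3 = mp.generate_dataset(mouse_model, sched, scheme, noise=noise, seed=6)
    assert not d3["value"].equals(d1["value"])


def test_preset_wilcock_po_nine_tissues():
    _, scheme = mp.preset_wilcock_po()
    tissues = set(scheme.times) - {"urine", "feces"}
    assert len(tissues) == 9
    for name in ("venous_plasma", "portal_vein", "enterocytes", "liver",
                 "kidney", "heart", "muscle", "adipose", "brain"):
        assert name in tissues
    assert "stomach" not in tissues  # unusable after oral dosing


def test_preset_wilcock_iv_includes_stomach():
    sched, scheme = mp.preset_wilcock_iv()
    assert "stomach" in scheme.times
    assert sched.events[0].route is mp.Route.IV


def test_preset_mouse_full_covers_all_partition_tissues():
    _, scheme = mp.preset_mouse_full()
    assert {"lungs", "remainder", "stomach"} <= set(scheme.times)
    assert set(MOUSE_TISSUE_CURVES) <= set(scheme.times)


def test_preset_zaharenko_urine_times():
    _, scheme = mp.preset_zaharenko()
    assert tuple(scheme.times["urine"]) == HUMAN_URINE_TIMES == (4.0, 6.0, 10.0, 24.0)


def test_preset_chung_predose_layout():
    sched, scheme = mp.preset_chung(375.0, 250.0)
    assert [e.amount_mg for e in sched.events] == [375.0, 250.0]
    assert sched.events[1].time == pytest.approx(12.0)
    assert min(scheme.times["venous_plasma"]) > 12.0


def test_urine_observations_cumulative(human_model):
    sched, scheme = mp.preset_zaharenko(500.0)
    data = mp.generate_dataset(human_model, sched, scheme, noise=None, seed=0)
    urine = data[data["curve"] == "urine"].sort_values("time_h")
    assert (np.diff(urine["value"]) > 0).all()
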