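import pytest

import metpbpk as mp
from metpbpk.species_models import (
    ABSORPTION_SCALED,
    ELIMINATION_SCALED,
    MissingParameterError,
    rescale_proctor_kinetics,
)


def test_compartment_counts(mouse_model, human_model):
    assert mouse_model.n == 20
    assert human_model.n == 21  # adds the red-blood-cell pool
    assert "rbc" in human_model.names
    assert "rbc" not in mouse_model.names


def test_flow_balance_both_species(mouse_model, human_model):
    mouse_model.validate_flow_balance()
    human_model.validate_flow_balance()


def test_lungs_carry_cardiac_output(mouse_model):
    cfg = mp.load_species_config("mouse")
    q_co = cfg["physiology"]["cardiac_output_plasma_mL_h"]
    assert mouse_model.reaction("Q:lungs:in").parameters["Q"] == pytest.approx(q_co)


def test_elimination_scaleup_factor(mouse_model, human_model):
    for rid in ELIMINATION_SCALED:
        vm_m = mouse_model.reaction(rid).parameters["Vmax"]
        vm_h = human_model.reaction(rid).parameters["Vmax"]
        km_m = mouse_model.reaction(rid).parameters["Km"]
        km_h = human_model.reaction(rid).parameters["Km"]
        assert vm_h / vm_m == pytest.approx(320.0)
        assert km_h == pytest.approx(km_m)  # affinities are conserved


def test_absorption_scaleup_factor(mouse_model, human_model):
    mouse_cfg = mp.load_species_config("mouse")
    human_cfg = mp.load_species_config("human")
    area_m = mouse_cfg["physiology"]["intestinal_surface_area_cm2"]
    area_h = human_cfg["physiology"]["intestinal_surface_area_cm2"]
    expected = 0.7 * area_h / area_m
    for rid in ABSORPTION_SCALED:
        pm = mouse_model.reaction(rid).parameters
        ph = human_model.reaction(rid).parameters
        key = "Vmax" if "Vmax" in pm else "Kd"
        assert ph[key] / pm[key] == pytest.approx(expected)


def test_proctor_rescaling():
    # 0.2 mg protein per cm^2: 1 nmol/h/mg over 100 cm^2 -> 20 nmol/h
    assert rescale_proctor_kinetics(1.0, 100.0, 0.2) == pytest.approx(20.0)


def test_reference_oct1_capacity(mouse_model):
    # whole-organ basolateral efflux capacity of the mouse reference model
    assert mouse_model.reaction("03.3").parameters["Vmax"] == pytest.approx(495.0)


def test_body_weight_scaling():
    light = mp.build_human_model(body_weight=35.0)
    ref = mp.build_human_model()
    assert light.volume("muscle") == pytest.approx(ref.volume("muscle") / 2)
    q_light = light.reaction("Q:lungs:in").parameters["Q"]
    q_ref = ref.reaction("Q:lungs:in").parameters["Q"]
    assert q_light == pytest.approx(q_ref / 2)
    # transporter capacities do not scale with body weight
    assert light.reaction("13.4").parameters["Vmax"] == pytest.approx(
        ref.reaction("13.4").parameters["Vmax"])


def test_scenario_modify_tissue(human_model):
    bigger = mp.scenario_modify_tissue(human_model, "muscle", 10_000.0)
    assert bigger.volume("muscle") == pytest.approx(
        human_model.volume("muscle") + 10_000.0)
    ratio = bigger.volume("muscle") / human_model.volume("muscle")
    q_old = human_model.reaction("Q:muscle:in").parameters["Q"]
    q_new = bigger.reaction("Q:muscle:in").parameters["Q"]
    assert q_new == pytest.approx(q_old * ratio)
    bigger.validate_flow_balance()


def test_scenario_rejects_nonpositive_volume(human_model):
    with pytest.raises(mp.InvalidParameterError):
        mp.scenario_modify_tissue(human_model, "muscle",
                                  -2 * human_model.volume("muscle"))


def test_missing_parameter_is_loud():
    cfg = mp.load_species_config("mouse")
    del cfg["physiology"]["gfr_mL_h"]
    with pytest.raises(MissingParameterError):
        mp.PhysiologyTable.from_config(cfg)


def test_custom_ktp_propagates():
    model = mp.build_mouse_model(ktp={**mp.load_species_config("mouse")
                                      ["partition_coefficients"], "liver": 9.0})
    assert model.compartment("liver").ktp == pytest.approx(9.0)
    assert model.reaction("Q:liver:out").parameters["partition"] == pytest.approx(9.0)


def test_load_parameter_csv_roundtrip(tmp_path):
    path = tmp_path / "params.csv"
    path.write_text("parameter,value,unit\n"
                    "physiology.volumes_mL.liver,1234.5,mL\n"
                    "body_weight_kg,60,kg\n")
    cfg = mp.load_parameter_csv(path)
    assert cfg["physiology"]["volumes_mL"]["liver"] == pytest.approx(1234.5)
    assert cfg["body_weight_kg"] == pytest.approx(60.0)
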