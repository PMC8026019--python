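import pytest

import metpbpk as mp


@pytest.fixture(scope="session")
def mouse_model():
    return mp.build_mouse_model()


@pytest.fixture(scope="session")
def human_model():
    return mp.build_human_model()


@pytest.fixture(scope="session")
def mouse_po_result(mouse_model):
    """50 mg/kg oral base dose in a 25 g mouse, 24 h."""
    schedule = mp.DoseSchedule.single(1.25, route="po", form="base")
    return mp.simulate(mouse_model, schedule, 24.0)


@pytest.fixture(scope="session")
def human_po_result(human_model):
    """500 mg hydrochloride single oral dose, 24 h."""
    schedule = mp.DoseSchedule.single(500.0, route="po", form="hydrochloride")
    return mp.simulate(human_model, schedule, 24.0)


@pytest.fixture(scope="session")
def human_bid_result(human_model):
    """500 mg hydrochloride twice daily, 8 doses, followed to 108 h."""
    schedule = mp.DoseSchedule.repeated(500.0, 8, 12.0, route="po",
                                        form="hydrochloride")
    return mp.simulate(human_model, schedule, 108.0)
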