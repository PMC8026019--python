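import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metpbpk as mp
from metpbpk.pk_metrics import (
    HalfLifeUndefinedError,
    amount_metrics,
    auc,
    cmax_tmax,
    steady_state_time,
    terminal_half_life,
)


def test_toy_curve_hand_values():
    # hand trapezoid: (0+10)/2 + (10+5)/2 = 12.5
    t, c = [0.0, 1.0, 2.0], [0.0, 10.0, 5.0]
    assert auc(t, c) == pytest.approx(12.5)
    assert cmax_tmax(t, c) == (10.0, 1.0)


def test_auc_partial_interval_interpolates():
    t, c = [0.0, 2.0], [0.0, 2.0]
    assert auc(t, c, t_end=1.0) == pytest.approx(0.5)


def test_auc_rejects_extrapolation():
    with pytest.raises(ValueError):
        auc([0.0, 1.0], [1.0, 1.0], t_end=2.0)


@settings(max_examples=30, deadline=None)
@given(values=st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=4,
                       max_size=20),
       split=st.integers(min_value=2, max_value=18))
def test_auc_additive_over_subintervals(values, split):
    t = np.arange(len(values), dtype=float)
    c = np.array(values)
    split = min(split, len(values) - 2)
    total = auc(t, c)
    left = auc(t[:split + 1], c[:split + 1])
    right = auc(t[split:], c[split:])
    assert left + right == pytest.approx(total, rel=1e-12, abs=1e-12)


def test_cmax_ties_resolve_to_earliest():
    assert cmax_tmax([0.0, 1.0, 2.0], [5.0, 5.0, 5.0]) == (5.0, 0.0)


def test_half_life_mono_exponential_exact():
    k = 0.21
    t = np.linspace(0.0, 30.0, 200)
    c = 8.0 * np.exp(-k * t)
    assert terminal_half_life(t, c) == pytest.approx(np.log(2) / k, rel=1e-10)


def test_half_life_needs_post_peak_points():
    with pytest.raises(HalfLifeUndefinedError):
        terminal_half_life([0.0, 1.0, 2.0], [0.0, 10.0, 5.0])


def test_half_life_rejects_rising_tail():
    t = np.linspace(0.0, 10.0, 50)
    with pytest.raises(HalfLifeUndefinedError):
        terminal_half_life(t, np.exp(0.1 * t))


def test_summarize_mouse_plasma(mouse_po_result):
    s = mp.summarize(mouse_po_result, "venous_plasma")
    assert s.cmax > 0 and 0 < s.tmax < 24 and s.auc24 > 0 and s.t_half > 0
    assert s.amount_at_cmax_mg > 0


def test_multidose_summary_human(human_bid_result):
    s = mp.multidose_summary(human_bid_result, "venous_plasma", tau=12.0)
    assert s.cmean is not None and 0 < s.cmean < s.cmax
    assert s.steady_state_reached
    # accumulation: the course-wide Cmax exceeds the first-dose peak
    t = human_bid_result.time
    c = human_bid_result.concentration("venous_plasma")
    first_peak = c[t <= 12.0].max()
    assert s.cmax > first_peak


def test_steady_state_time_plasma_before_rbc(human_bid_result):
    """Plasma equilibrates within days; the RBC pool keeps accumulating."""
    t_plasma = steady_state_time(human_bid_result, "venous_plasma", tau=12.0)
    t_rbc = steady_state_time(human_bid_result, "rbc", tau=12.0)
    assert np.isfinite(t_plasma)
    assert t_rbc > t_plasma


def test_steady_state_requires_multidose(human_po_result):
    with pytest.raises(ValueError):
        steady_state_time(human_po_result, "venous_plasma", tau=12.0)


def test_amount_metrics_fractions(mouse_po_result):
    df = amount_metrics(mouse_po_result)
    assert (df["peak_amount_mg"] >= 0).all()
    assert "urine" not in set(df["tissue"])
    muscle = df.set_index("tissue").loc["muscle"]
    assert 0 < muscle["peak_fraction_of_absorbed"] < 1.5


def test_oscillation_metrics(human_bid_result):
    amp_p, mean_p = mp.oscillation_metrics(human_bid_result, "venous_plasma",
                                           tau=12.0)
    amp_r, mean_r = mp.oscillation_metrics(human_bid_result, "rbc", tau=12.0)
    assert amp_p > 0 and mean_p > 0
    # the slow RBC pool oscillates much less, relative to its mean
    assert amp_r / mean_r < amp_p / mean_p


def test_summary_table_layout(human_po_result):
    table = mp.summary_table(human_po_result, dose_mg=500.0)
    assert "venous_plasma" in set(table["tissue"])
    assert "rbc" in set(table["tissue"])
    assert (table["auc24_nmol_h_per_mL"] > 0).all()
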