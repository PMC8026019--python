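"""Synthetic concentration-time datasets for recovery studies and demos.

A sampling scheme maps curve names (model compartments, or the urine/feces
sinks for cumulative amounts) to sampling times. Datasets are generated by
simulating the model, reading the curves at the scheme times and optionally
applying multiplicative lognormal measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import validate_dataset
from .model_core import DoseEvent, DoseForm, DoseSchedule, ModelDefinition, Route
from .ode_engine import SolverOptions, simulate

#: Sparse sampling grid of the mouse tissue-distribution experiments, h.
MOUSE_TIMES = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
#: Human plasma / red-blood-cell sampling grid, h.
HUMAN_PLASMA_TIMES = (1.0, 2.0, 3.0, 4.0, 6.0, 10.0, 24.0)
#: Human cumulative-urine collection end points, h.
HUMAN_URINE_TIMES = (4.0, 6.0, 10.0, 24.0)

#: The nine tissue curves reported by the oral mouse distribution
#: experiments ("enterocytes" stands for the intestinal-tissue homogenate;
#: stomach tissue is only usable after intravenous dosing).
MOUSE_TISSUE_CURVES = ("venous_plasma", "portal_vein", "brain", "muscle",
                       "adipose", "heart", "liver", "kidney", "enterocytes")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement error with a given CV.

    Observed = true * exp(eps), eps ~ N(-sigma^2/2, sigma^2) with
    sigma^2 = ln(1 + cv^2), so the expectation of the observed value equals
    the true value and its coefficient of variation equals ``cv``.
    """

    cv: float = 0.1

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv ** 2)))

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(values, dtype=float).copy()
        s = self.sigma
        eps = rng.normal(-0.5 * s * s, s, size=np.shape(values))
        return np.asarray(values, dtype=float) * np.exp(eps)


@dataclass(frozen=True)
class SamplingScheme:
    """Curve names mapped to their sampling times (h)."""

    times: Mapping[str, Sequence[float]]
    label: str = "custom"

    def __post_init__(self):
        for curve, ts in self.times.items():
            ts = np.asarray(ts, dtype=float)
            if len(ts) == 0 or (ts <= 0).any() or (np.diff(ts) <= 0).any():
                raise ValueError(
                    f"times for {curve!r} must be positive and increasing")

    @property
    def t_last(self) -> float:
        return max(max(ts) for ts in self.times.values())


def generate_dataset(model: ModelDefinition, schedule: DoseSchedule,
                     scheme: SamplingScheme,
                     noise: NoiseModel | None = None,
                     seed: int | None = None,
                     duration: float | None = None,
                     opts: SolverOptions | None = None) -> pd.DataFrame:
    """Simulate ``model`` under ``schedule`` and sample it per ``scheme``.

    With ``noise=None`` the dataset is noiseless (exact model output at the
    scheme times). Randomness is fully determined by ``seed``.
    """
    duration = duration if duration is not None else scheme.t_last
    result = simulate(model, schedule, duration, opts)
    rng = np.random.default_rng(seed)
    rows = []
    for curve in sorted(scheme.times):
        ts = np.asarray(scheme.times[curve], dtype=float)
        if curve == model.urine:
            series = result.cumulative_urine
        elif curve == model.feces:
            series = result.cumulative_feces
        else:
            series = result.concentration(curve)
        values = np.interp(ts, result.time, series)
        if noise is not None:
            values = noise.apply(values, rng)
        for t, v in zip(ts, values):
            rows.append({"curve": curve, "time_h": t, "value": float(v)})
    return validate_dataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# preset experimental designs
# ---------------------------------------------------------------------------

def preset_wilcock_po(dose_mg_per_kg: float = 50.0,
                      body_weight_kg: float = 0.025) -> tuple[DoseSchedule, SamplingScheme]:
    """Mouse oral tissue-distribution design: one PO base dose, ten tissue
    curves plus cumulative urine and feces at the sparse mouse grid."""
    times = {c: MOUSE_TIMES for c in MOUSE_TISSUE_CURVES}
    times["urine"] = MOUSE_TIMES
    times["feces"] = MOUSE_TIMES
    schedule = DoseSchedule.single(dose_mg_per_kg * body_weight_kg,
                                   route=Route.PO, form="base")
    return schedule, SamplingScheme(times, label="mouse_po")


def preset_wilcock_iv(dose_mg_per_kg: float = 50.0,
                      body_weight_kg: float = 0.025) -> tuple[DoseSchedule, SamplingScheme]:
    """Mouse intravenous companion design: same grid, IV bolus, and the
    stomach-tissue curve becomes usable (no unabsorbed luminal drug)."""
    times = {c: MOUSE_TIMES for c in MOUSE_TISSUE_CURVES + ("stomach",)}
    times["urine"] = MOUSE_TIMES
    schedule = DoseSchedule.single(dose_mg_per_kg * body_weight_kg,
                                   route=Route.IV, form="base")
    return schedule, SamplingScheme(times, label="mouse_iv")


def preset_mouse_full(dose_mg_per_kg: float = 50.0,
                      body_weight_kg: float = 0.025,
                      route: Route | str = Route.PO) -> tuple[DoseSchedule, SamplingScheme]:
    """Extended mouse design sampling *every* partitioning tissue (adds
    stomach, lungs and the remainder pool), used for full
    partition-coefficient recovery."""
    curves = MOUSE_TISSUE_CURVES + ("stomach", "lungs", "remainder")
    times = {c: MOUSE_TIMES for c in curves}
    times["urine"] = MOUSE_TIMES
    if Route(route) is Route.PO:  # no fecal excretion after an IV bolus
        times["feces"] = MOUSE_TIMES
    schedule = DoseSchedule.single(dose_mg_per_kg * body_weight_kg,
                                   route=route, form="base")
    return schedule, SamplingScheme(times, label="mouse_full")


def preset_zaharenko(dose_mg_hcl: float = 500.0) -> tuple[DoseSchedule, SamplingScheme]:
    """Human single-dose design: one PO hydrochloride dose; venous plasma and
    red-blood-cell concentrations plus cumulative urinary excretion."""
    times = {
        "venous_plasma": HUMAN_PLASMA_TIMES,
        "rbc": HUMAN_PLASMA_TIMES,
        "urine": HUMAN_URINE_TIMES,
    }
    schedule = DoseSchedule.single(dose_mg_hcl, route=Route.PO,
                                   form="hydrochloride")
    return schedule, SamplingScheme(times, label="human_single")


def preset_chung(pre_dose_mg_hcl: float = 375.0,
                 main_dose_mg_hcl: float = 250.0,
                 lead_h: float = 12.0) -> tuple[DoseSchedule, SamplingScheme]:
    """Human pre-dose plasma design: a lead hydrochloride dose followed
    ``lead_h`` hours later by the main dose; plasma sampled relative to the
    main dose. (The lead dose is placed at t = 0, so all times are >= 0.)"""
    schedule = DoseSchedule((
        DoseEvent(0.0, pre_dose_mg_hcl, Route.PO, DoseForm.hydrochloride),
        DoseEvent(lead_h, main_dose_mg_hcl, Route.PO, DoseForm.hydrochloride),
    ))
    rel = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0])
    times = {"venous_plasma": tuple(lead_h + rel)}
    return schedule, SamplingScheme(times, label="human_predose")
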