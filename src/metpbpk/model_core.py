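"""Domain types and rate-law primitives for whole-body PBPK models of metformin.

Internal units are fixed throughout the package: amounts in nmol, volumes in
mL, time in h, concentrations in nmol/mL, flows and clearances in mL/h.
Doses cross the boundary in mg (free base or hydrochloride salt) and are
converted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

#: Molar mass of metformin free base, g/mol.
METFORMIN_MOLAR_MASS = 129.16

#: Mass fraction of metformin free base in metformin hydrochloride
#: (1000 mg HCl salt corresponds to 778.4 mg free base).
SALT_TO_BASE = 0.7784


def mg_to_nmol(mg: float) -> float:
    """Convert mg of metformin free base to nmol."""
    return mg * 1e6 / METFORMIN_MOLAR_MASS


def nmol_to_mg(nmol: float) -> float:
    """Convert nmol of metformin to mg of free base."""
    return nmol * METFORMIN_MOLAR_MASS / 1e6


def hydrochloride_to_base_mg(mg_hcl: float) -> float:
    """Convert mg of metformin hydrochloride to mg of free base."""
    return mg_hcl * SALT_TO_BASE


class InvalidParameterError(ValueError):
    """A kinetic or structural parameter violates its domain."""


class InvalidStateError(ValueError):
    """A state variable (amount/concentration) violates its domain."""


# ---------------------------------------------------------------------------
# rate-law primitives
# ---------------------------------------------------------------------------

def flow_exchange_rate(Q: float, C_source: float, C_tissue: float,
                       Ktp: float = 1.0) -> float:
    """Net convective/diffusive exchange rate ``Q * (C_source - C_tissue/Ktp)``.

    Parameters
    ----------
    Q : flow or permeability clearance, mL/h (>= 0).
    C_source, C_tissue : concentrations on the two sides, nmol/mL.
    Ktp : tissue:plasma partition coefficient of the tissue side (> 0).

    Returns the net rate in nmol/h; a positive sign moves mass from source
    to tissue.
    """
    if Ktp <= 0:
        raise InvalidParameterError(f"Ktp must be > 0, got {Ktp}")
    if Q < 0:
        raise InvalidParameterError(f"Q must be >= 0, got {Q}")
    return Q * (C_source - C_tissue / Ktp)


def michaelis_menten_rate(Vmax: float, Km: float, S: float) -> float:
    """Saturable carrier-mediated transport rate ``Vmax * S / (Km + S)``."""
    if Vmax < 0:
        raise InvalidParameterError(f"Vmax must be >= 0, got {Vmax}")
    if Km <= 0:
        raise InvalidParameterError(f"Km must be > 0, got {Km}")
    if S < 0:
        raise InvalidStateError(f"substrate concentration must be >= 0, got {S}")
    return Vmax * S / (Km + S)


def linear_transport_rate(Kd: float, S: float) -> float:
    """Non-saturable (diffusive) transport rate ``Kd * S``."""
    if Kd < 0:
        raise InvalidParameterError(f"Kd must be >= 0, got {Kd}")
    return Kd * S


def renal_clearance_total(Q_GFR: float, CL_active: float) -> float:
    """Total renal clearance: glomerular filtration plus active secretion."""
    if Q_GFR < 0 or CL_active < 0:
        raise InvalidParameterError("clearances must be >= 0")
    return Q_GFR + CL_active


# ---------------------------------------------------------------------------
# structural types
# ---------------------------------------------------------------------------

class CompartmentKind(str, Enum):
    tissue_well_stirred = "tissue_well_stirred"
    vascular = "vascular"
    lumen = "lumen"
    excreta = "excreta"


@dataclass(frozen=True)
class Compartment:
    """A physiological compartment: an organ, a fluid space or an excreta sink.

    ``ktp`` (tissue:plasma partition coefficient) is meaningful only for
    well-stirred tissue compartments.
    """

    name: str
    volume: float  # mL; excreta sinks carry a nominal volume of 1.0
    kind: CompartmentKind = CompartmentKind.tissue_well_stirred
    ktp: float | None = None

    def __post_init__(self):
        if self.kind is not CompartmentKind.excreta and self.volume <= 0:
            raise InvalidParameterError(
                f"compartment {self.name!r}: volume must be > 0, got {self.volume}")
        if self.kind is CompartmentKind.tissue_well_stirred:
            if self.ktp is not None and self.ktp <= 0:
                raise InvalidParameterError(
                    f"compartment {self.name!r}: Ktp must be > 0, got {self.ktp}")


class RateForm(str, Enum):
    #: unidirectional convective outflow ``Q/partition * C_source``
    flow = "flow"
    #: bidirectional exchange ``Q * (C_source - C_sink/partition)``
    flow_exchange = "flow_exchange"
    michaelis_menten = "michaelis_menten"
    linear = "linear"
    gfr_filtration = "gfr_filtration"
    #: first-order in amount, ``k * A_source`` (lumen/tubular transit)
    first_order = "first_order"


_REQUIRED_PARAMS = {
    RateForm.flow: {"Q"},
    RateForm.flow_exchange: {"Q"},
    RateForm.michaelis_menten: {"Vmax", "Km"},
    RateForm.linear: {"Kd"},
    RateForm.gfr_filtration: {"Q_GFR"},
    RateForm.first_order: {"k"},
}


@dataclass(frozen=True)
class RateLaw:
    """One mass-transfer reaction between two compartments.

    ``rid`` follows the deposited models' naming scheme, e.g.
    "03.2 IntestineLumen -> Enterocytes (PMAT OCT3)", so that cross-species
    scaling coefficients can target reactions by stable identifiers.
    """

    rid: str
    form: RateForm
    source: str
    sink: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.source == self.sink:
            raise InvalidParameterError(f"{self.rid}: source == sink ({self.source})")
        missing = _REQUIRED_PARAMS[self.form] - set(self.parameters)
        if missing:
            raise InvalidParameterError(f"{self.rid}: missing parameters {missing}")
        for key, val in self.parameters.items():
            if key in ("Q", "Vmax", "Kd", "Q_GFR", "k") and val < 0:
                raise InvalidParameterError(f"{self.rid}: {key} must be >= 0, got {val}")
            if key in ("Km", "partition") and val <= 0:
                raise InvalidParameterError(f"{self.rid}: {key} must be > 0, got {val}")


class Route(str, Enum):
    PO = "po"
    IV = "iv"


class DoseForm(str, Enum):
    hydrochloride = "hydrochloride"
    base = "base"


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: ``amount_mg`` of metformin at ``time`` h.

    ``form`` states whether the amount is hydrochloride salt (the clinical
    unit) or free base (used for the mouse experiments); conversion to nmol of
    free base happens when the dose is applied.
    """

    time: float
    amount_mg: float
    route: Route = Route.PO
    form: DoseForm = DoseForm.hydrochloride

    def __post_init__(self):
        if self.amount_mg < 0:
            raise InvalidParameterError(f"dose amount must be >= 0, got {self.amount_mg}")
        if self.time < 0:
            raise InvalidParameterError(f"dose time must be >= 0, got {self.time}")

    @property
    def amount_nmol(self) -> float:
        mg_base = (hydrochloride_to_base_mg(self.amount_mg)
                   if self.form is DoseForm.hydrochloride else self.amount_mg)
        return mg_to_nmol(mg_base)


@dataclass(frozen=True)
class DoseSchedule:
    events: tuple[DoseEvent, ...]

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidParameterError("dose times must be non-decreasing")

    @classmethod
    def single(cls, amount_mg: float, route: Route | str = Route.PO,
               form: DoseForm | str = DoseForm.hydrochloride,
               time: float = 0.0) -> "DoseSchedule":
        return cls((DoseEvent(time, amount_mg, Route(route), DoseForm(form)),))

    @classmethod
    def repeated(cls, amount_mg: float, n_doses: int, interval_h: float,
                 route: Route | str = Route.PO,
                 form: DoseForm | str = DoseForm.hydrochloride) -> "DoseSchedule":
        return cls(tuple(DoseEvent(i * interval_h, amount_mg, Route(route),
                                   DoseForm(form)) for i in range(n_doses)))

    @property
    def total_nmol(self) -> float:
        return sum(e.amount_nmol for e in self.events)

    @property
    def last_time(self) -> float:
        return max((e.time for e in self.events), default=0.0)


class TopologyError(ValueError):
    """The compartment/flow wiring violates a structural invariant."""


@dataclass
class ModelDefinition:
    """A complete species model: compartments, reactions and entry points."""

    species: str
    body_weight: float  # kg
    compartments: list[Compartment]
    reactions: list[RateLaw]
    entry_po: str = "stomach_lumen"
    entry_iv: str = "venous_plasma"
    urine: str = "urine"
    feces: str = "feces"

    def __post_init__(self):
        names = [c.name for c in self.compartments]
        if len(names) != len(set(names)):
            raise TopologyError("duplicate compartment names")
        self._index = {n: i for i, n in enumerate(names)}
        known = set(names)
        for r in self.reactions:
            for endpoint in (r.source, r.sink):
                if endpoint not in known:
                    raise TopologyError(f"{r.rid}: unknown compartment {endpoint!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    @property
    def n(self) -> int:
        return len(self.compartments)

    def index(self, name: str) -> int:
        return self._index[name]

    def compartment(self, name: str) -> Compartment:
        return self.compartments[self._index[name]]

    def volume(self, name: str) -> float:
        return self.compartment(name).volume

    def reaction(self, rid: str) -> RateLaw:
        for r in self.reactions:
            if r.rid == rid:
                return r
        raise KeyError(rid)

    def validate_flow_balance(self, rtol: float = 1e-9) -> None:
        """Check convective-flow conservation at every vascular node.

        At each vascular compartment the sum of ``flow``-form inflows must
        equal the sum of outflows (cardiac-output consistency; GFR and
        carrier fluxes are not plasma flows and are excluded).
        """
        inflow: dict[str, float] = {c.name: 0.0 for c in self.compartments}
        outflow: dict[str, float] = {c.name: 0.0 for c in self.compartments}
        for r in self.reactions:
            if r.form is RateForm.flow:
                q = r.parameters["Q"]
                outflow[r.source] += q
                inflow[r.sink] += q
        for c in self.compartments:
            if c.kind is not CompartmentKind.vascular:
                continue
            q_in, q_out = inflow[c.name], outflow[c.name]
            scale = max(q_in, q_out, 1.0)
            if not math.isclose(q_in, q_out, rel_tol=rtol, abs_tol=rtol * scale):
                raise TopologyError(
                    f"flow imbalance at {c.name!r}: in={q_in:.6g} out={q_out:.6g} mL/h")
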