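"""Assemble the mouse (20-compartment) and human (21-compartment) models.

Both species share one structure: eleven organs plus plasma pools wired by
arterial/venous/portal plasma flow, a three-compartment small intestine
(lumen / enterocytes / intestinal vasculature) carrying all absorption, and a
three-compartment kidney (renal plasma / renal tissue / proximal-tubular
lumen) carrying all elimination via glomerular filtration plus OCT2/MATE
active secretion. The human model adds a red-blood-cell compartment that
exchanges slowly with venous plasma and is excluded from the flow topology.

The human model is a scale-up of the mouse model: partition coefficients are
carried over unchanged, intestinal carrier capacities are rescaled by
intestinal surface area times an absorption coefficient (applied to reactions
03.2, 03.3, 03.4, 03.6, 03.7), and renal secretion capacities by an
elimination coefficient (applied to reactions 13.4 and 13.5).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

from .model_core import (
    Compartment,
    CompartmentKind,
    InvalidParameterError,
    ModelDefinition,
    RateForm,
    RateLaw,
    TopologyError,
)

#: Human-readable labels for the reaction identifiers used in both models.
REACTION_LABELS = {
    "03.1": "StomachLumen -> IntestineLumen (gastric emptying)",
    "03.2": "IntestineLumen -> Enterocytes (PMAT OCT3)",
    "03.3": "Enterocytes -> IntestineVascular (OCT1)",
    "03.4": "IntestineLumen -> IntestineVascular (Saturable)",
    "03.5": "IntestineLumen -> Feces (intestinal transit)",
    "03.6": "IntestineLumen -> Enterocytes (Diffusion)",
    "03.7": "IntestineLumen -> IntestineVascular (Diffusion)",
    "03.8": "IntestineVascular <-> Enterocytes (Diffusion)",
    "12.1": "KidneyPlasma -> KidneyTubular (GFR)",
    "12.2": "KidneyTubular -> Urine (tubular transit)",
    "13.4": "KidneyPlasma -> KidneyTissue (OCT2)",
    "13.5": "KidneyTissue -> KidneyTubular (MATE1 MATE2-K OCT1)",
    "13.6": "KidneyPlasma <-> KidneyTissue (Diffusion)",
    "15.1": "VenousPlasma <-> RBC (Diffusion)",
}

#: Reactions whose capacity constants are multiplied by the absorption
#: coefficient during mouse -> human scale-up.
ABSORPTION_SCALED = ("03.2", "03.3", "03.4", "03.6", "03.7")
#: Reactions multiplied by the elimination coefficient.
ELIMINATION_SCALED = ("13.4", "13.5")

_WELL_STIRRED = ("lungs", "heart", "brain", "muscle", "adipose", "remainder")


class MissingParameterError(KeyError):
    """A required physiological or kinetic parameter is absent from the config."""


@dataclass
class PhysiologyTable:
    """Species physiology: volumes, plasma flows and transit rates.

    The remainder compartment's volume and flow are computed as the total
    minus the named tissues and must come out positive.
    """

    body_weight: float  # kg
    total_volume: float  # mL
    cardiac_output: float  # plasma flow, mL/h
    gfr: float  # mL/h
    urine_flow: float  # mL/h
    gastric_emptying: float  # 1/h
    intestinal_transit: float  # 1/h
    volumes: dict[str, float]  # mL per named compartment
    flows: dict[str, float]  # mL/h per named tissue (plasma)
    hematocrit: float | None = None
    intestinal_surface_area: float = 0.0  # cm^2
    protein_per_area: float = 0.2  # mg/cm^2
    tubular_transit: float | None = None  # 1/h; default gfr / V_tubular

    @classmethod
    def from_config(cls, cfg: Mapping) -> "PhysiologyTable":
        phys = cfg["physiology"]
        try:
            return cls(
                body_weight=cfg["body_weight_kg"],
                total_volume=phys["total_volume_mL"],
                cardiac_output=phys["cardiac_output_plasma_mL_h"],
                gfr=phys["gfr_mL_h"],
                urine_flow=phys["urine_flow_mL_h"],
                gastric_emptying=phys["gastric_emptying_per_h"],
                intestinal_transit=phys["intestinal_transit_per_h"],
                hematocrit=phys.get("hematocrit"),
                intestinal_surface_area=phys["intestinal_surface_area_cm2"],
                protein_per_area=phys["protein_per_area_mg_cm2"],
                tubular_transit=phys.get("tubular_transit_per_h"),
                volumes=dict(phys["volumes_mL"]),
                flows=dict(phys["flows_mL_h"]),
            )
        except KeyError as exc:  # flag loudly which parameter is missing
            raise MissingParameterError(
                f"physiology table is missing parameter {exc}") from exc

    @property
    def remainder_volume(self) -> float:
        v = self.total_volume - sum(self.volumes.values())
        if v <= 0:
            raise InvalidParameterError(
                f"remainder volume must be > 0, got {v:.4g} mL")
        return v

    @property
    def remainder_flow(self) -> float:
        q = self.cardiac_output - sum(self.flows.values())
        if q <= 0:
            raise InvalidParameterError(
                f"remainder plasma flow must be > 0, got {q:.4g} mL/h")
        return q

    @property
    def protein_mass(self) -> float:
        """Total intestinal monolayer-equivalent protein, mg."""
        return self.intestinal_surface_area * self.protein_per_area

    def scaled(self, body_weight: float) -> "PhysiologyTable":
        """Linear allometry: volumes and flows scale with body weight."""
        s = body_weight / self.body_weight
        return replace(
            self, body_weight=body_weight,
            total_volume=self.total_volume * s,
            cardiac_output=self.cardiac_output * s,
            gfr=self.gfr * s, urine_flow=self.urine_flow * s,
            volumes={k: v * s for k, v in self.volumes.items()},
            flows={k: q * s for k, q in self.flows.items()},
        )


@dataclass(frozen=True)
class ScaleUpCoefficients:
    """Mouse -> human scaling of transporter capacities."""

    absorption_coef: float = 0.7
    elimination_coef: float = 320.0

    def __post_init__(self):
        if self.absorption_coef <= 0 or self.elimination_coef <= 0:
            raise InvalidParameterError("scale-up coefficients must be > 0")


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def load_species_config(species_or_path: str) -> dict:
    """Load a parameter config: builtin species name ('mouse'/'human') or path."""
    if species_or_path in ("mouse", "human"):
        ref = resources.files("metpbpk.parameters") / f"{species_or_path}_synthetic.yaml"
        text = ref.read_text()
    else:
        with open(species_or_path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def load_parameter_csv(path) -> dict:
    """Read a flat parameter CSV (parameter name, value, unit) into a config.

    Dotted parameter names map to nested config keys, e.g.
    ``physiology.volumes_mL.liver, 1800, mL``.
    """
    cfg: dict = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().startswith("#") or row[0].strip() == "parameter":
                continue
            name, value = row[0].strip(), row[1].strip()
            node = cfg
            *parents, leaf = name.split(".")
            for key in parents:
                node = node.setdefault(key, {})
            try:
                node[leaf] = float(value)
            except ValueError:
                node[leaf] = value
    return cfg


def rescale_proctor_kinetics(value_per_mg_protein: float, surface_area_cm2: float,
                             protein_density_mg_per_cm2: float) -> float:
    """Scale an in vitro monolayer kinetic constant to the whole organ.

    Caco-2 monolayer constants are reported per mg protein; 1 cm^2 of
    monolayer carries ``protein_density`` mg of protein, so the whole-organ
    value is value x density x area.
    """
    if value_per_mg_protein < 0 or surface_area_cm2 < 0 or protein_density_mg_per_cm2 < 0:
        raise InvalidParameterError("Proctor rescaling arguments must be >= 0")
    return value_per_mg_protein * protein_density_mg_per_cm2 * surface_area_cm2


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _organ_intestinal_kinetics(per_mg: Mapping, protein_mass: float,
                               absorption_coef: float = 1.0) -> dict:
    """Whole-organ intestinal kinetics from per-mg-protein constants."""
    out: dict[str, dict[str, float]] = {}
    for rid in ("03.2", "03.3", "03.4"):
        p = per_mg[rid]
        vkey = "Vf" if "Vf" in p else "Vmax"
        out[rid] = {"Vmax": p[vkey] * protein_mass * absorption_coef, "Km": p["Km"]}
    for rid in ("03.6", "03.7"):
        out[rid] = {"Kd": per_mg[rid]["Kd"] * protein_mass * absorption_coef}
    return out


def _assemble(species: str, phys: PhysiologyTable, ktp: Mapping[str, float],
              intestinal: Mapping, renal: Mapping, passive: Mapping,
              rbc: Mapping | None = None) -> ModelDefinition:
    V = dict(phys.volumes)
    V["remainder"] = phys.remainder_volume
    Q = dict(phys.flows)
    Q["remainder"] = phys.remainder_flow

    def need(mapping, key, what):
        try:
            return mapping[key]
        except KeyError as exc:
            raise MissingParameterError(f"missing {what} {key!r}") from exc

    comps = [
        Compartment("venous_plasma", need(V, "venous_plasma", "volume"),
                    CompartmentKind.vascular),
        Compartment("arterial_plasma", need(V, "arterial_plasma", "volume"),
                    CompartmentKind.vascular),
        Compartment("portal_vein", need(V, "portal_vein", "volume"),
                    CompartmentKind.vascular),
        Compartment("lungs", need(V, "lungs", "volume"), ktp=need(ktp, "lungs", "Ktp")),
        Compartment("heart", V["heart"], ktp=need(ktp, "heart", "Ktp")),
        Compartment("brain", V["brain"], ktp=need(ktp, "brain", "Ktp")),
        Compartment("muscle", V["muscle"], ktp=need(ktp, "muscle", "Ktp")),
        Compartment("adipose", V["adipose"], ktp=need(ktp, "adipose", "Ktp")),
        Compartment("remainder", V["remainder"], ktp=need(ktp, "remainder", "Ktp")),
        Compartment("stomach", V["stomach"], ktp=need(ktp, "stomach", "Ktp")),
        Compartment("liver", V["liver"], ktp=need(ktp, "liver", "Ktp")),
        Compartment("stomach_lumen", V["stomach_lumen"], CompartmentKind.lumen),
        Compartment("intestine_lumen", V["intestine_lumen"], CompartmentKind.lumen),
        Compartment("enterocytes", V["enterocytes"],
                    ktp=need(ktp, "intestine", "Ktp")),
        Compartment("intestine_vascular", V["intestine_vascular"],
                    CompartmentKind.vascular),
        Compartment("kidney_plasma", V["kidney_plasma"], CompartmentKind.vascular),
        Compartment("kidney", V["kidney"], ktp=need(ktp, "kidney", "Ktp")),
        Compartment("kidney_tubular", V["kidney_tubular"], CompartmentKind.lumen),
        Compartment("urine", 1.0, CompartmentKind.excreta),
        Compartment("feces", 1.0, CompartmentKind.excreta),
    ]
    if rbc is not None:
        comps.append(Compartment("rbc", need(V, "rbc", "volume"),
                                 CompartmentKind.vascular))

    R: list[RateLaw] = []

    def flow(rid, src, sink, q, partition=None):
        params = {"Q": q}
        if partition is not None:
            params["partition"] = partition
        R.append(RateLaw(rid, RateForm.flow, src, sink, params))

    q_co = phys.cardiac_output
    flow("Q:lungs:in", "venous_plasma", "lungs", q_co)
    flow("Q:lungs:out", "lungs", "arterial_plasma", q_co, ktp["lungs"])
    for t in ("heart", "brain", "muscle", "adipose", "remainder"):
        flow(f"Q:{t}:in", "arterial_plasma", t, Q[t])
        flow(f"Q:{t}:out", t, "venous_plasma", Q[t], ktp[t])
    flow("Q:stomach:in", "arterial_plasma", "stomach", Q["stomach"])
    flow("Q:stomach:out", "stomach", "portal_vein", Q["stomach"], ktp["stomach"])
    flow("Q:intestine_vascular:in", "arterial_plasma", "intestine_vascular",
         Q["intestine"])
    flow("Q:intestine_vascular:out", "intestine_vascular", "portal_vein",
         Q["intestine"])
    q_portal = Q["stomach"] + Q["intestine"]
    flow("Q:portal_vein:out", "portal_vein", "liver", q_portal)
    flow("Q:liver:in", "arterial_plasma", "liver", Q["liver_arterial"])
    flow("Q:liver:out", "liver", "venous_plasma", Q["liver_arterial"] + q_portal,
         ktp["liver"])
    flow("Q:kidney_plasma:in", "arterial_plasma", "kidney_plasma", Q["kidney"])
    flow("Q:kidney_plasma:out", "kidney_plasma", "venous_plasma", Q["kidney"])

    # gastrointestinal transit + absorption
    R.append(RateLaw("03.1", RateForm.first_order, "stomach_lumen",
                     "intestine_lumen", {"k": phys.gastric_emptying}))
    R.append(RateLaw("03.5", RateForm.first_order, "intestine_lumen", "feces",
                     {"k": phys.intestinal_transit}))
    R.append(RateLaw("03.2", RateForm.michaelis_menten, "intestine_lumen",
                     "enterocytes", dict(intestinal["03.2"])))
    R.append(RateLaw("03.3", RateForm.michaelis_menten, "enterocytes",
                     "intestine_vascular", dict(intestinal["03.3"])))
    R.append(RateLaw("03.4", RateForm.michaelis_menten, "intestine_lumen",
                     "intestine_vascular", dict(intestinal["03.4"])))
    R.append(RateLaw("03.6", RateForm.linear, "intestine_lumen", "enterocytes",
                     dict(intestinal["03.6"])))
    R.append(RateLaw("03.7", RateForm.linear, "intestine_lumen",
                     "intestine_vascular", dict(intestinal["03.7"])))
    R.append(RateLaw("03.8", RateForm.flow_exchange, "intestine_vascular",
                     "enterocytes",
                     {"Q": need(passive, "enterocyte_exchange_Kd", "passive Kd"),
                      "partition": ktp["intestine"]}))

    # renal filtration, secretion and tubular transit
    R.append(RateLaw("12.1", RateForm.gfr_filtration, "kidney_plasma",
                     "kidney_tubular", {"Q_GFR": phys.gfr}))
    k_tub = (phys.tubular_transit if phys.tubular_transit is not None
             else phys.gfr / V["kidney_tubular"])
    R.append(RateLaw("12.2", RateForm.first_order, "kidney_tubular", "urine",
                     {"k": k_tub}))
    R.append(RateLaw("13.4", RateForm.michaelis_menten, "kidney_plasma",
                     "kidney", dict(need(renal, "13.4", "renal kinetics"))))
    R.append(RateLaw("13.5", RateForm.michaelis_menten, "kidney",
                     "kidney_tubular", dict(need(renal, "13.5", "renal kinetics"))))
    R.append(RateLaw("13.6", RateForm.flow_exchange, "kidney_plasma", "kidney",
                     {"Q": need(passive, "kidney_exchange_Kd", "passive Kd"),
                      "partition": ktp["kidney"]}))

    if rbc is not None:
        kin = need(rbc, "kin_mL_h", "RBC exchange")
        kout = need(rbc, "kout_mL_h", "RBC exchange")
        if kin > 0 and kout > 0:
            R.append(RateLaw("15.1", RateForm.flow_exchange, "venous_plasma",
                             "rbc", {"Q": kin, "partition": kin / kout}))

    model = ModelDefinition(species=species, body_weight=phys.body_weight,
                            compartments=comps, reactions=R)
    model.validate_flow_balance()
    return model


def build_mouse_model(phys: PhysiologyTable | None = None,
                      kinetics: Mapping | None = None,
                      ktp: Mapping[str, float] | None = None) -> ModelDefinition:
    """Build the 20-compartment mouse model from a physiology table and
    kinetic parameter map (defaults: the packaged reference parameterization)."""
    cfg = load_species_config("mouse")
    phys = phys or PhysiologyTable.from_config(cfg)
    kinetics = kinetics if kinetics is not None else cfg["kinetics"]
    ktp = dict(ktp if ktp is not None else cfg["partition_coefficients"])
    intestinal = _organ_intestinal_kinetics(
        kinetics["intestinal_per_mg_protein"], phys.protein_mass)
    return _assemble("mouse", phys, ktp, intestinal, kinetics["renal"],
                     kinetics["passive"])


def build_human_model(phys: PhysiologyTable | None = None,
                      kinetics: Mapping | None = None,
                      coefs: ScaleUpCoefficients | None = None,
                      body_weight: float | None = None,
                      ktp: Mapping[str, float] | None = None,
                      local: Mapping | None = None) -> ModelDefinition:
    """Build the 21-compartment human model by scale-up from mouse kinetics.

    ``kinetics`` is the *mouse* kinetic map (per-mg intestinal constants and
    whole-organ renal constants); the absorption coefficient multiplies the
    capacity constants of reactions 03.2, 03.3, 03.4, 03.6 and 03.7 and the
    elimination coefficient those of 13.4 and 13.5. Partition coefficients
    default to the mouse values unchanged. Volumes and flows scale linearly
    with ``body_weight`` relative to the 70 kg reference.
    """
    cfg = load_species_config("human")
    mouse_cfg = load_species_config("mouse")
    phys = phys or PhysiologyTable.from_config(cfg)
    if body_weight is not None and body_weight != phys.body_weight:
        phys = phys.scaled(body_weight)
    kinetics = kinetics if kinetics is not None else mouse_cfg["kinetics"]
    ktp = dict(ktp if ktp is not None else mouse_cfg["partition_coefficients"])
    scale = cfg.get("scale_up", {})
    coefs = coefs or ScaleUpCoefficients(scale.get("absorption_coef", 0.7),
                                         scale.get("elimination_coef", 320.0))
    local = local if local is not None else cfg["kinetics_local"]

    intestinal = _organ_intestinal_kinetics(
        kinetics["intestinal_per_mg_protein"], phys.protein_mass,
        coefs.absorption_coef)
    renal = {
        rid: {"Vmax": kinetics["renal"][rid]["Vmax"] * coefs.elimination_coef,
              "Km": kinetics["renal"][rid]["Km"]}
        for rid in ELIMINATION_SCALED
    }
    return _assemble("human", phys, ktp, intestinal, renal,
                     local["passive"], rbc=local["rbc"])


def scenario_modify_tissue(model: ModelDefinition, tissue: str,
                           volume_delta: float) -> ModelDefinition:
    """Individualization scenario: grow/shrink a tissue with proportional flow.

    The tissue's blood flow scales with the new/old volume ratio and the
    cardiac output (the lung through-flow) grows by the same absolute flow
    increment, emulating e.g. a trained subject (more muscle) or obesity
    (more adipose).
    """
    try:
        comp = model.compartment(tissue)
    except KeyError as exc:
        raise KeyError(f"tissue {tissue!r} not found") from exc
    new_volume = comp.volume + volume_delta
    if new_volume <= 0:
        raise InvalidParameterError(f"resulting volume must be > 0, got {new_volume}")
    ratio = new_volume / comp.volume

    rid_in, rid_out = f"Q:{tissue}:in", f"Q:{tissue}:out"
    try:
        q_old = model.reaction(rid_in).parameters["Q"]
    except KeyError as exc:
        raise TopologyError(f"{tissue!r} has no dedicated flow reactions") from exc
    dq = q_old * (ratio - 1.0)

    comps = [replace(c, volume=new_volume) if c.name == tissue else c
             for c in model.compartments]
    reactions = []
    for r in model.reactions:
        if r.rid in (rid_in, rid_out):
            params = dict(r.parameters)
            params["Q"] = params["Q"] * ratio
            r = replace(r, parameters=params)
        elif r.rid in ("Q:lungs:in", "Q:lungs:out"):
            params = dict(r.parameters)
            params["Q"] = params["Q"] + dq
            r = replace(r, parameters=params)
        reactions.append(r)
    out = ModelDefinition(species=model.species, body_weight=model.body_weight,
                          compartments=comps, reactions=reactions,
                          entry_po=model.entry_po, entry_iv=model.entry_iv,
                          urine=model.urine, feces=model.feces)
    out.validate_flow_balance()
    return out
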