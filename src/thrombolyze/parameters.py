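"""Typed registry of model constants, species, scenarios and unit conventions.

Unit conventions
----------------
Internally everything is SI (m, s, Pa, L for plasma volume) except
concentrations, which are expressed in μM throughout.  Conversions from
clinical units (mg/dL, mg/kg doses, half-lives in minutes) happen only at
the I/O boundary, i.e. in :func:`load_parameters` and
:func:`mass_to_molar`.

Every constant carries a provenance tag so that values fixed by the
study design, taken from supplementary material, adopted from the
classical fibrinolysis modelling literature, or chosen here as defaults
remain auditable.  Tags: ``paper-main``, ``paper-SI``,
``prior-publication``, ``default``.
"""

from __future__ import annotations

import math
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "MOBILE_SPECIES",
    "PLATELET_SPECIES",
    "BOUND_SPECIES",
    "Phase",
    "Species",
    "DoseRegimen",
    "Scenario",
    "ParameterSet",
    "load_parameters",
    "default_parameters",
    "builtin_scenarios",
    "get_scenario",
    "mass_to_molar",
    "molar_to_mass",
]

PROVENANCE_TAGS = ("paper-main", "paper-SI", "prior-publication", "default")

#: Mobile plasma-phase species transported by the 1D model and resolved by
#: the systemic compartment model (order is the canonical state ordering).
MOBILE_SPECIES = ("tPA", "PLG", "PLS", "AP", "AP_PLS", "FBG", "MG", "PAI", "NV", "NVemp")

#: Cellular species: activated platelets and their vesicle-bound tallies.
PLATELET_SPECIES = ("PLT_tot", "PLT_NV", "PLT_NVemp")

#: Fibrin-bound species plus the intact-binding-site field n_FBR.
BOUND_SPECIES = ("tPA_F", "PLG_F", "PLS_F", "PLS_F_lysed", "n_FBR")

ALL_FIELDS = MOBILE_SPECIES + PLATELET_SPECIES + BOUND_SPECIES


class Phase(str, Enum):
    MOBILE_PLASMA = "mobile-plasma"
    MOBILE_CELLULAR = "mobile-cellular"
    BOUND = "bound"


class Species(BaseModel):
    """A model species: phase, diffusivity and (if dosed) molecular weight."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    phase: Phase
    diffusivity: float | None = None  # m^2/s, mobile species only
    molecular_weight: float | None = None  # g/mol, dosed species only

    @model_validator(mode="after")
    def _check(self) -> "Species":
        if self.phase in (Phase.MOBILE_PLASMA, Phase.MOBILE_CELLULAR):
            if self.diffusivity is None or self.diffusivity <= 0:
                raise ValueError(f"mobile species {self.name!r} needs diffusivity > 0")
        return self


class DoseRegimen(BaseModel):
    """Bolus + continuous-infusion dosing schedule.

    The total dose is prescribed per kg body weight, as in the standard
    stroke regimen (0.9 mg/kg, 10% bolus, remainder infused over 1 h).
    The bolus is a finite top-hat (default 5 s), not a Dirac impulse.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    total_dose: float = Field(gt=0, description="mg per kg body weight")
    body_weight: float = Field(default=70.0, gt=0, description="kg")
    bolus_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    bolus_duration: float = Field(default=5.0, gt=0, description="s")
    infusion_duration: float = Field(default=3600.0, gt=0, description="s")

    @property
    def total_mass(self) -> float:
        """Total administered drug mass in mg."""
        return self.total_dose * self.body_weight


class Scenario(BaseModel):
    """One treatment scenario: clot geometry/composition, drug and inlet mode."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    description: str = ""
    d_clot: float = Field(ge=0, description="clot offset from inlet, m")
    l_clot: float = Field(gt=0, description="clot length, m")
    phi_fbr0: float = Field(ge=0, lt=1, description="initial fibrin volume fraction")
    phi_plt0: float = Field(ge=0, lt=1, description="initial platelet volume fraction")
    drug: str = Field(description="'tPA' or 'NV'")
    inlet_mode: str = Field(default="constant", description="'constant' or 'systemic-PKPD'")
    regimen: DoseRegimen | None = None
    inlet_concentration: float | None = Field(
        default=None, description="constant drug inlet concentration, μM (None → therapeutic default)"
    )

    @field_validator("drug")
    @classmethod
    def _drug(cls, v: str) -> str:
        if v not in ("tPA", "NV"):
            raise ValueError("drug must be 'tPA' or 'NV'")
        return v

    @field_validator("inlet_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("constant", "systemic-PKPD"):
            raise ValueError("inlet_mode must be 'constant' or 'systemic-PKPD'")
        return v

    @model_validator(mode="after")
    def _composition(self) -> "Scenario":
        if self.phi_fbr0 + self.phi_plt0 >= 1.0:
            raise ValueError("phi_fbr0 + phi_plt0 must be < 1")
        if self.inlet_mode == "systemic-PKPD" and self.regimen is None:
            raise ValueError(f"scenario {self.name!r}: systemic-PKPD inlet requires a regimen")
        return self

    @property
    def porosity0(self) -> float:
        """Initial clot porosity ε0 = 1 − φ_FBR,0 − φ_PLT,0."""
        return 1.0 - self.phi_fbr0 - self.phi_plt0

    @property
    def domain_length(self) -> float:
        return self.d_clot + self.l_clot


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesParams(_Section):
    """Diffusivities (m²/s) and molecular weights (g/mol)."""

    d_tpa: float = Field(gt=0)
    d_plg: float = Field(gt=0)
    d_pls: float = Field(gt=0)
    d_ap: float = Field(gt=0)
    d_ap_pls: float = Field(gt=0)
    d_fbg: float = Field(gt=0)
    d_mg: float = Field(gt=0)
    d_pai: float = Field(gt=0)
    d_nv: float = Field(gt=0)
    d_nvemp: float = Field(gt=0)
    d_plt: float = Field(gt=0)
    mw_tpa: float = Field(gt=0)
    mw_fbg: float = Field(gt=0)


class KineticsParams(_Section):
    """Rate constants of the fibrinolysis + nanovesicle reaction network.

    Second-order constants are in 1/(μM·s); first-order and catalytic
    constants in 1/s; Michaelis constants in μM.
    """

    k_cat_plg_plasma: float = Field(ge=0)
    km_plg_plasma: float = Field(gt=0)
    k_ap: float = Field(ge=0)
    k_mg: float = Field(ge=0)
    k_pai: float = Field(ge=0)
    k_cat_fbg: float = Field(ge=0)
    km_fbg: float = Field(gt=0)
    k_leak: float = Field(ge=0)
    k_on_nv: float = Field(ge=0)
    k_off_nv: float = Field(ge=0)
    k_off_nvemp: float = Field(ge=0)
    k_trig: float = Field(ge=0)
    k_trig_base: float = Field(default=0.0, ge=0)
    hill_release: float = Field(default=1.0, gt=0)
    c_plt_ref: float = Field(
        default=5.535e-6, gt=0,
        description="reference platelet concentration for the release law, μM",
    )
    k_on_tpa: float = Field(ge=0)
    k_off_tpa: float = Field(ge=0)
    k_on_plg: float = Field(ge=0)
    k_off_plg: float = Field(ge=0)
    k_on_pls: float = Field(ge=0)
    k_off_pls: float = Field(ge=0)
    k_cat_plg_bound: float = Field(ge=0)
    km_plg_bound: float = Field(gt=0)
    k_deg: float = Field(ge=0)
    k_deg_sat: float = Field(gt=0, description="site saturation scale of r_deg, μM")
    k_rel_lysed: float = Field(ge=0)
    v_rel: float = Field(gt=0, description="moles tPA encapsulated per mole NV")


class HemodynamicsParams(_Section):
    """Vessel, flow and clot-microstructure constants (SI units)."""

    mu: float = Field(gt=0, description="blood viscosity, Pa·s")
    dpdx: float = Field(ge=0, description="pressure drop per unit length, Pa/m")
    area: float = Field(gt=0, description="vessel cross-section, m²")
    r_f: float = Field(gt=0, description="fibrin fibre radius, m")
    r_p: float = Field(gt=0, description="platelet effective radius, m")
    platelet_volume: float = Field(gt=0, description="single-platelet volume, m³")
    n_int: float = Field(gt=0, description="integrins per activated platelet")
    n_fbr_0: float = Field(
        gt=0, description="initial fibrin binding-site concentration in the clot, μM"
    )
    m_mobility: float = Field(gt=0, description="mobility slope constant m")
    e_l_crit: float = Field(gt=0, lt=1, description="critical extent of lysis")


class PKParams(_Section):
    """Systemic one-compartment constants: volumes, clearances, baselines."""

    v_c: float = Field(gt=0, description="plasma volume, L")
    body_weight: float = Field(default=70.0, gt=0, description="kg")
    inlet_tpa: float = Field(gt=0, description="therapeutic constant-inlet tPA level, μM")
    # half-lives in seconds; k_el = ln 2 / t_half
    t_half_tpa: float = Field(gt=0)
    t_half_nv: float = Field(gt=0)
    t_half_plg: float = Field(gt=0)
    t_half_pls: float = Field(gt=0)
    t_half_ap: float = Field(gt=0)
    t_half_ap_pls: float = Field(gt=0)
    t_half_fbg: float = Field(gt=0)
    t_half_mg: float = Field(gt=0)
    t_half_pai: float = Field(gt=0)
    # baseline (pre-treatment) plasma concentrations, μM
    c0_tpa: float = Field(ge=0)
    c0_plg: float = Field(ge=0)
    c0_pls: float = Field(ge=0)
    c0_ap: float = Field(ge=0)
    c0_ap_pls: float = Field(ge=0)
    c0_fbg: float = Field(ge=0)
    c0_mg: float = Field(ge=0)
    c0_pai: float = Field(ge=0)


class SolverParams(_Section):
    """Discretisation and integration settings."""

    dx: float = Field(default=2.0e-5, gt=0, description="grid spacing, m")
    dt_report: float = Field(default=1.0, gt=0, description="reporting / hemodynamic refresh interval, s")
    rtol: float = Field(default=1.0e-6, gt=0)
    atol: float = Field(default=1.0e-12, gt=0, description="μM")
    t_max: float = Field(default=1800.0, gt=0, description="s")
    u_max: float = Field(default=0.1, gt=0, description="cap on permeation velocity, m/s")
    snapshot_interval: float = Field(default=30.0, gt=0, description="field snapshot cadence, s")
    bc_relax_tau: float = Field(default=0.05, gt=0, description="inlet Dirichlet relaxation time, s")
    lysis_complete_threshold: float = Field(default=0.999, gt=0, le=1.0)


class ParameterSet(BaseModel):
    """Single source of truth for all model constants.

    Attributes mirror the config sections; ``provenance`` maps
    ``section.key`` to one of the provenance tags.
    """

    model_config = ConfigDict(extra="forbid")

    species: SpeciesParams
    kinetics: KineticsParams
    hemodynamics: HemodynamicsParams
    pk: PKParams
    solver: SolverParams = SolverParams()
    provenance: dict[str, str] = Field(default_factory=dict)

    @field_validator("provenance")
    @classmethod
    def _tags(cls, v: dict[str, str]) -> dict[str, str]:
        for key, tag in v.items():
            if tag not in PROVENANCE_TAGS:
                raise ValueError(f"unknown provenance tag {tag!r} for {key!r}")
        return v

    # -- derived quantities -------------------------------------------------

    @property
    def mw_nv(self) -> float:
        """Payload-equivalent NV molecular weight, g/mol.

        NV doses are prescribed in tPA-equivalent mass (the study doses the
        'equivalent NV amount'), so one mole of NV weighs v_rel moles of tPA.
        """
        return self.kinetics.v_rel * self.species.mw_tpa

    def k_el(self, species: str) -> float:
        """Elimination rate constant, 1/s, from the configured half-life."""
        t = {
            "tPA": self.pk.t_half_tpa,
            "NV": self.pk.t_half_nv,
            "NVemp": self.pk.t_half_nv,  # empty NV cleared like loaded NV
            "PLG": self.pk.t_half_plg,
            "PLS": self.pk.t_half_pls,
            "AP": self.pk.t_half_ap,
            "AP_PLS": self.pk.t_half_ap_pls,
            "FBG": self.pk.t_half_fbg,
            "MG": self.pk.t_half_mg,
            "PAI": self.pk.t_half_pai,
        }[species]
        return math.log(2.0) / t

    def baseline(self, species: str) -> float:
        """Baseline plasma concentration, μM."""
        return {
            "tPA": self.pk.c0_tpa,
            "PLG": self.pk.c0_plg,
            "PLS": self.pk.c0_pls,
            "AP": self.pk.c0_ap,
            "AP_PLS": self.pk.c0_ap_pls,
            "FBG": self.pk.c0_fbg,
            "MG": self.pk.c0_mg,
            "PAI": self.pk.c0_pai,
            "NV": 0.0,
            "NVemp": 0.0,
        }[species]

    def secretion(self, species: str) -> float:
        """Homeostatic secretion rate S_i = k_el,i · C_i,0 (μM/s).

        Endogenous proteins are secreted at exactly their clearance rate so
        that the drug-free system is stationary; dosed/derived species
        (NV, NVemp, PLS, AP-PLS) are not secreted.
        """
        if species in ("NV", "NVemp", "PLS", "AP_PLS"):
            return 0.0
        return self.k_el(species) * self.baseline(species)

    def diffusivity(self, species: str) -> float:
        s = self.species
        return {
            "tPA": s.d_tpa, "PLG": s.d_plg, "PLS": s.d_pls, "AP": s.d_ap,
            "AP_PLS": s.d_ap_pls, "FBG": s.d_fbg, "MG": s.d_mg, "PAI": s.d_pai,
            "NV": s.d_nv, "NVemp": s.d_nvemp, "PLT": s.d_plt,
        }[species]

    def c_plt0(self, phi_plt0: float) -> float:
        """Initial platelet concentration (μM) from the platelet volume fraction."""
        n_per_m3 = phi_plt0 / self.hemodynamics.platelet_volume
        mol_per_l = n_per_m3 / 6.02214076e23 / 1.0e3
        return mol_per_l * 1.0e6

    def n_fbr0(self, phi_fbr0: float) -> float:
        """Initial fibrin binding-site concentration (μM).

        Uniform over the clot and common to all scenarios (sites are set by
        the fibre radius, not the bulk fibrin fraction); zero if the clot
        has no fibrin at all.
        """
        return self.hemodynamics.n_fbr_0 if phi_fbr0 > 0 else 0.0

    def inlet_nv(self) -> float:
        """Constant-inlet NV concentration equivalent to the therapeutic
        tPA level: C_NV,in = C_tPA,in / v_rel (μM)."""
        return self.pk.inlet_tpa / self.kinetics.v_rel

    def species_registry(self) -> list[Species]:
        """The full species table (enumeration, phases, diffusivities)."""
        out = []
        for name in MOBILE_SPECIES:
            mw = None
            if name == "tPA":
                mw = self.species.mw_tpa
            elif name == "FBG":
                mw = self.species.mw_fbg
            elif name in ("NV", "NVemp"):
                mw = self.mw_nv
            out.append(
                Species(name=name, phase=Phase.MOBILE_PLASMA,
                        diffusivity=self.diffusivity(name), molecular_weight=mw)
            )
        for name in PLATELET_SPECIES:
            out.append(
                Species(name=name, phase=Phase.MOBILE_CELLULAR,
                        diffusivity=self.species.d_plt)
            )
        out.append(Species(name="FDP", phase=Phase.MOBILE_PLASMA,
                           diffusivity=self.species.d_fbg))
        for name in BOUND_SPECIES:
            out.append(Species(name=name, phase=Phase.BOUND))
        return out


# ---------------------------------------------------------------------------
# config loading


def _flatten(section: str, mapping: Mapping[str, Any]) -> tuple[dict[str, float], dict[str, str]]:
    """Split {key: value | {value, provenance}} into values + provenance."""
    values: dict[str, Any] = {}
    prov: dict[str, str] = {}
    for key, raw in mapping.items():
        if isinstance(raw, Mapping):
            unknown = set(raw) - {"value", "provenance", "units", "comment"}
            if unknown:
                raise ValueError(f"[{section}] {key}: unknown entry fields {sorted(unknown)}")
            if "value" not in raw:
                raise ValueError(f"[{section}] {key}: missing 'value'")
            values[key] = raw["value"]
            prov[f"{section}.{key}"] = raw.get("provenance", "default")
        else:
            values[key] = raw
            prov[f"{section}.{key}"] = "default"
    return values, prov


def _parameters_from_dict(doc: Mapping[str, Any]) -> ParameterSet:
    sections = {"species", "kinetics", "hemodynamics", "pk", "solver"}
    unknown = set(doc) - sections - {"scenario", "regimen"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    missing = {"species", "kinetics", "hemodynamics", "pk"} - set(doc)
    if missing:
        raise ValueError(f"missing config sections: {sorted(missing)}")
    payload: dict[str, Any] = {}
    provenance: dict[str, str] = {}
    for section in sections & set(doc):
        values, prov = _flatten(section, doc[section])
        payload[section] = values
        provenance.update(prov)
    payload["provenance"] = provenance
    return ParameterSet(**payload)


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load and validate a YAML parameter file.

    Each leaf may be a plain number or ``{value: x, provenance: tag,
    units: "...", comment: "..."}``.  Unknown sections or keys are
    rejected; half-lives are given in seconds in the file.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"parameter file {path} does not contain a mapping")
    return _parameters_from_dict(doc)


def default_parameters() -> ParameterSet:
    """The canonical parameter set shipped with the package."""
    ref = resources.files("thrombolyze.data").joinpath("default_parameters.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)


def scenario_from_config(config_path: str | Path) -> Scenario | None:
    """Extract the optional [scenario]/[regimen] sections of a config file."""
    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    if "scenario" not in doc:
        return None
    scen = dict(doc["scenario"])
    if "regimen" in doc:
        scen["regimen"] = DoseRegimen(**doc["regimen"])
    return Scenario(**scen)


# ---------------------------------------------------------------------------
# built-in scenario table


_STANDARD = dict(total_dose=0.9, bolus_fraction=0.1, bolus_duration=5.0, infusion_duration=3600.0)


def builtin_scenarios(body_weight: float = 70.0) -> list[Scenario]:
    """The sixteen built-in treatment scenarios.

    S1–S12 vary clot position and composition under constant inlet
    concentrations; S13–S16 couple the systemic PKPD model with different
    dosing regimens on the same proximal dense clot.
    """
    mm = 1.0e-3

    def s(name, desc, d, l, ff, fp, drug, mode, regimen=None):
        return Scenario(
            name=name, description=desc, d_clot=d * mm, l_clot=l * mm,
            phi_fbr0=ff, phi_plt0=fp, drug=drug, inlet_mode=mode, regimen=regimen,
        )

    def reg(total_dose, bolus_fraction=0.1, infusion_duration=3600.0):
        return DoseRegimen(
            total_dose=total_dose, body_weight=body_weight,
            bolus_fraction=bolus_fraction, bolus_duration=5.0,
            infusion_duration=infusion_duration,
        )

    return [
        s("S1", "Distal dense PLT-poor clot", 2, 4, 0.02, 0.03, "tPA", "constant"),
        s("S2", "Distal dense PLT-poor clot", 2, 4, 0.02, 0.03, "NV", "constant"),
        s("S3", "Proximal dense PLT-poor clot", 0, 4, 0.02, 0.03, "tPA", "constant"),
        s("S4", "Proximal dense PLT-poor clot", 0, 4, 0.02, 0.03, "NV", "constant"),
        s("S5", "Proximal dense PLT-rich clot", 0, 4, 0.01, 0.04, "tPA", "constant"),
        s("S6", "Proximal dense PLT-rich clot", 0, 4, 0.01, 0.04, "NV", "constant"),
        s("S7", "Proximal coarse clot", 0, 4, 0.01, 0.01, "tPA", "constant"),
        s("S8", "Proximal coarse clot", 0, 4, 0.01, 0.01, "NV", "constant"),
        s("S9", "Proximal coarse PLT-poor clot", 0, 4, 0.015, 0.005, "tPA", "constant"),
        s("S10", "Proximal coarse PLT-poor clot", 0, 4, 0.015, 0.005, "NV", "constant"),
        s("S11", "Proximal coarse PLT-rich clot", 0, 4, 0.005, 0.015, "tPA", "constant"),
        s("S12", "Proximal coarse PLT-rich clot", 0, 4, 0.005, 0.015, "NV", "constant"),
        s("S13", "Standard regimen, recommended dose 0.9 mg/kg", 0, 4, 0.02, 0.03,
          "tPA", "systemic-PKPD", reg(0.9)),
        s("S14", "Standard regimen, recommended dose", 0, 4, 0.02, 0.03,
          "NV", "systemic-PKPD", reg(0.9)),
        s("S15", "Bolus only, 10% recommended dose", 0, 4, 0.02, 0.03,
          "NV", "systemic-PKPD",
          DoseRegimen(total_dose=0.09, body_weight=body_weight, bolus_fraction=1.0,
                      bolus_duration=5.0, infusion_duration=3600.0)),
        s("S16", "Standard regimen, 50% recommended dose", 0, 4, 0.02, 0.03,
          "NV", "systemic-PKPD", reg(0.45)),
    ]


def get_scenario(name: str, body_weight: float = 70.0) -> Scenario:
    for scen in builtin_scenarios(body_weight):
        if scen.name == name:
            return scen
    raise KeyError(f"unknown scenario {name!r}")


# ---------------------------------------------------------------------------
# unit conversions


def mass_to_molar(mass_conc: float, mw: float) -> float:
    """Convert mg/dL to μM.

    mg/dL → g/L is ×0.01; dividing by Mw (g/mol) gives mol/L; ×1e6 gives μM.
    E.g. the 150 mg/dL fibrinogen bleeding-risk threshold is ≈ 4.4 μM.
    """
    if mass_conc < 0:
        raise ValueError("mass concentration must be >= 0")
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    return mass_conc * 0.01 / mw * 1.0e6


def molar_to_mass(molar_conc: float, mw: float) -> float:
    """Convert μM to mg/dL (inverse of :func:`mass_to_molar`)."""
    if molar_conc < 0:
        raise ValueError("molar concentration must be >= 0")
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    return molar_conc * 1.0e-6 * mw * 100.0
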