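"""Reference adult physiology, virtual populations, and disease scaling.

This module supplies the anatomy/physiology side of the PBPK model: organ
volumes and blood flows for a reference adult (ICRP-style table shipped in
``data/reference_physiology.yaml``), log-normal population variability, and
stage-wise pathophysiology for liver cirrhosis (Child-Pugh A/B/C) and chronic
kidney disease (moderate/severe).

Conventions
-----------
* Volumes in L, flows in L/h, GFR in mL/min/1.73 m^2, times in min.
* ``organ_blood_flows['liver']`` is the hepatic *artery* flow; total hepatic
  blood flow ``QH`` is hepatic artery + portal inflow (gut + spleen).
* Cardiac output is defined as the sum of all arterial organ flows, so flow
  balance holds by construction and is re-checked after every transformation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "IndividualPhysiology",
    "PopulationSpec",
    "DiseaseSpec",
    "PhysiologyError",
    "load_reference_table",
    "load_disease_table",
    "build_reference_adult",
    "sample_population",
    "apply_disease",
    "population_to_frame",
    "DISEASE_STAGES",
]

DISEASE_STAGES = ("healthy", "CP-A", "CP-B", "CP-C", "CKD-moderate", "CKD-severe")

#: organs expected in every physiology record (blood pools listed separately)
TISSUE_ORGANS = (
    "lung", "liver", "kidney", "gut", "muscle", "adipose", "skin",
    "bone", "brain", "heart", "spleen", "rest",
)
BLOOD_POOLS = ("arterial_blood", "venous_blood")
#: organs perfused from the arterial pool (lung sits in series after venous return)
ARTERIAL_ORGANS = (
    "liver", "gut", "spleen", "kidney", "muscle", "adipose", "skin",
    "bone", "brain", "heart", "rest",
)


class PhysiologyError(ValueError):
    """Invalid demographic input or physiologically impossible value."""


def _load_yaml(name: str) -> dict:
    with resources.files("hcqpbpk.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_reference_table() -> dict:
    """Return the shipped reference-physiology table (parsed YAML)."""
    return _load_yaml("reference_physiology.yaml")


def load_disease_table() -> Dict[str, dict]:
    """Return the shipped disease-stage scaler table (parsed YAML)."""
    return _load_yaml("disease_scalers.yaml")


@dataclass
class IndividualPhysiology:
    """Anatomy/physiology of one virtual subject.

    ``enzyme_activity`` holds relative hepatic CYP activities (1.0 = healthy);
    disease scaling reduces them, and the clearance model multiplies intrinsic
    clearance by the contribution-weighted activity.
    """

    subject_id: str
    sex: str                       # 'F' | 'M'
    age: float                     # years
    body_weight: float             # kg
    hematocrit: float              # fraction of blood volume
    organ_volumes: Dict[str, float]        # organ -> L
    organ_blood_flows: Dict[str, float]    # organ -> L/h (arterial side)
    GFR: float                     # mL/min/1.73 m^2
    binding_protein_scalar: float = 1.0    # AGP multiplier, 1.0 = healthy
    gastric_emptying_time: float = 15.0    # min
    small_intestinal_transit_time: float = 210.0  # min
    enzyme_activity: Dict[str, float] = field(default_factory=dict)
    stage: str = "healthy"

    @property
    def cardiac_output(self) -> float:
        """L/h; sum of arterial organ flows (series lung carries all of it)."""
        return float(sum(self.organ_blood_flows.values()))

    @property
    def hepatic_blood_flow_QH(self) -> float:
        """Total hepatic blood flow: hepatic artery + portal (gut + spleen)."""
        f = self.organ_blood_flows
        return f["liver"] + f["gut"] + f["spleen"]

    def validate(self) -> "IndividualPhysiology":
        if self.sex not in ("F", "M"):
            raise PhysiologyError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not 0.0 < self.hematocrit < 1.0:
            raise PhysiologyError(f"hematocrit must lie in (0,1), got {self.hematocrit}")
        for name in TISSUE_ORGANS + BLOOD_POOLS:
            if name not in self.organ_volumes:
                raise PhysiologyError(f"missing organ volume: {name}")
            if self.organ_volumes[name] <= 0:
                raise PhysiologyError(f"organ volume must be > 0: {name}")
        for name in ARTERIAL_ORGANS:
            if name not in self.organ_blood_flows:
                raise PhysiologyError(f"missing organ blood flow: {name}")
            if self.organ_blood_flows[name] <= 0:
                raise PhysiologyError(f"organ blood flow must be > 0: {name}")
        if self.GFR <= 0:
            raise PhysiologyError(f"GFR must be > 0, got {self.GFR}")
        if self.binding_protein_scalar <= 0:
            raise PhysiologyError("binding_protein_scalar must be > 0")
        if self.gastric_emptying_time <= 0 or self.small_intestinal_transit_time <= 0:
            raise PhysiologyError("GI transit times must be > 0")
        # flow conservation: organ outflows re-sum to cardiac output
        co = self.cardiac_output
        if not np.isclose(sum(self.organ_blood_flows[o] for o in ARTERIAL_ORGANS), co,
                          rtol=1e-6, atol=0.0):
            raise PhysiologyError("organ flows do not balance cardiac output")
        return self


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual population sample."""

    n: int
    female_fraction: float = 0.6
    age_range: Tuple[float, float] = (19.0, 27.0)
    weight_range: Tuple[float, float] = (55.0, 68.0)
    variability_cv: Mapping[str, float] = field(
        default_factory=lambda: {
            "organ_volumes": 0.2,
            "organ_blood_flows": 0.2,
            "hematocrit": 0.05,
            "body_weight": 0.2,
        }
    )
    seed: int = 0

    def validate(self) -> "PopulationSpec":
        if self.n < 1:
            raise PhysiologyError("population size n must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise PhysiologyError("female_fraction must lie in [0,1]")
        if any(cv < 0 for cv in self.variability_cv.values()):
            raise PhysiologyError("all CVs must be >= 0")
        return self


@dataclass(frozen=True)
class DiseaseSpec:
    """A disease stage plus its physiology scalers/overrides."""

    stage: str
    scalers: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def from_stage(cls, stage: str, table: Mapping[str, dict] | None = None) -> "DiseaseSpec":
        table = table if table is not None else load_disease_table()
        if stage not in table:
            raise PhysiologyError(
                f"unknown disease stage {stage!r}; known: {sorted(table)}")
        return cls(stage=stage, scalers=table[stage] or {})


def table_reference(sex: str = "F",
                    reference_table: Mapping | None = None) -> IndividualPhysiology:
    """The shipped reference adult at its own table body weight (scale 1)."""
    table = reference_table if reference_table is not None else load_reference_table()
    ref = table["reference"][sex]
    return build_reference_adult(sex, 30.0, float(ref["body_weight"]),
                                 subject_id=f"ref-{sex}", reference_table=table)


def build_reference_adult(
    sex: str,
    age: float,
    weight: float,
    subject_id: str = "ref",
    reference_table: Mapping | None = None,
) -> IndividualPhysiology:
    """Construct a deterministic reference adult scaled to body weight.

    Organ volumes and flows come from the shipped ICRP-style table and are
    scaled by ``(weight / reference_weight) ** allometric_exponent`` (linear
    by default).  GFR, hematocrit and GI transit times are size-invariant.
    """
    table = reference_table if reference_table is not None else load_reference_table()
    if sex not in ("F", "M"):
        raise PhysiologyError(f"sex must be 'F' or 'M', got {sex!r}")
    if not 18.0 <= age <= 65.0:
        raise PhysiologyError(f"age must lie in [18, 65] years, got {age}")
    if not 40.0 <= weight <= 130.0:
        raise PhysiologyError(f"body weight must lie in [40, 130] kg, got {weight}")

    ref = table["reference"][sex]
    exponent = float(table.get("allometric_exponent", 1.0))
    scale = (weight / float(ref["body_weight"])) ** exponent
    volumes = {k: float(v) * scale for k, v in ref["organ_volumes"].items()}
    co = float(ref["cardiac_output"]) * scale
    flows = {organ: frac * co for organ, frac in table["flow_fractions"].items()}

    return IndividualPhysiology(
        subject_id=subject_id,
        sex=sex,
        age=float(age),
        body_weight=float(weight),
        hematocrit=float(ref["hematocrit"]),
        organ_volumes=volumes,
        organ_blood_flows=flows,
        GFR=float(ref["GFR"]),
        gastric_emptying_time=float(ref["gastric_emptying_time"]),
        small_intestinal_transit_time=float(ref["small_intestinal_transit_time"]),
        enzyme_activity={"CYP3A4": 1.0, "CYP2C8": 1.0, "CYP2D6": 1.0},
    ).validate()


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one log-normal multiplier(s) with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def sample_population(
    spec: PopulationSpec,
    reference_table: Mapping | None = None,
) -> list[IndividualPhysiology]:
    """Draw a seeded virtual population around the reference adult.

    Demographics: the female count is ``round(n * female_fraction)`` exactly;
    age is uniform on ``age_range``; weight is a mean-one log-normal around the
    mid-range (CV from ``variability_cv['body_weight']``), clipped to the
    40-130 kg validity window.  Organ volumes, flows and hematocrit receive
    independent mean-one log-normal perturbation; flows then re-balance
    (cardiac output := sum of perturbed flows), keeping conservation exact.
    """
    spec.validate()
    table = reference_table if reference_table is not None else load_reference_table()
    rng = np.random.default_rng(spec.seed)
    n_female = int(round(spec.n * spec.female_fraction))
    cv = dict(spec.variability_cv)

    individuals = []
    mid_weight = 0.5 * (spec.weight_range[0] + spec.weight_range[1])
    for i in range(spec.n):
        sex = "F" if i < n_female else "M"
        age = rng.uniform(*spec.age_range)
        weight = float(np.clip(
            mid_weight * _lognormal_factor(rng, cv.get("body_weight", 0.0)),
            40.0, 130.0))
        ind = build_reference_adult(sex, age, weight,
                                    subject_id=f"S{i + 1:04d}",
                                    reference_table=table)
        vol_cv = cv.get("organ_volumes", 0.0)
        flow_cv = cv.get("organ_blood_flows", 0.0)
        ind.organ_volumes = {k: v * float(_lognormal_factor(rng, vol_cv))
                             for k, v in ind.organ_volumes.items()}
        ind.organ_blood_flows = {k: q * float(_lognormal_factor(rng, flow_cv))
                                 for k, q in ind.organ_blood_flows.items()}
        hct = ind.hematocrit * float(_lognormal_factor(rng, cv.get("hematocrit", 0.0)))
        ind.hematocrit = float(np.clip(hct, 0.05, 0.70))
        individuals.append(ind.validate())
    return individuals


def apply_disease(physiology: IndividualPhysiology, disease: DiseaseSpec) -> IndividualPhysiology:
    """Return a new physiology with the stage's scalers applied.

    The input is left untouched.  ``hepatic_flow`` scales the whole splanchnic
    inflow (hepatic artery, gut, spleen), so QH scales with it; per-organ
    ``organ_flow`` multipliers follow; cardiac output is then re-derived as the
    sum of scaled flows, which keeps the balance invariant exact.
    """
    if disease.stage not in DISEASE_STAGES:
        raise PhysiologyError(
            f"unknown disease stage {disease.stage!r}; known: {list(DISEASE_STAGES)}")
    out = copy.deepcopy(physiology)
    out.stage = disease.stage
    s = dict(disease.scalers)
    if not s:
        return out.validate()

    def _positive(name: str, value: float) -> float:
        if value <= 0:
            raise PhysiologyError(f"disease scaler produced non-positive {name}: {value}")
        return value

    if "hepatic_flow" in s:
        for organ in ("liver", "gut", "spleen"):
            out.organ_blood_flows[organ] = _positive(
                f"flow[{organ}]", out.organ_blood_flows[organ] * float(s["hepatic_flow"]))
    for organ, mult in dict(s.get("organ_flow", {})).items():
        out.organ_blood_flows[organ] = _positive(
            f"flow[{organ}]", out.organ_blood_flows[organ] * float(mult))
    if "liver_volume" in s:
        out.organ_volumes["liver"] = _positive(
            "liver volume", out.organ_volumes["liver"] * float(s["liver_volume"]))
    if "hematocrit" in s:
        out.hematocrit = _positive("hematocrit", out.hematocrit * float(s["hematocrit"]))
    if "binding_protein" in s:
        out.binding_protein_scalar = _positive(
            "binding_protein_scalar",
            out.binding_protein_scalar * float(s["binding_protein"]))
    if "GFR_override" in s:
        out.GFR = _positive("GFR", float(s["GFR_override"]))
    elif "gfr" in s:
        out.GFR = _positive("GFR", out.GFR * float(s["gfr"]))
    if "gastric_emptying_time" in s:
        out.gastric_emptying_time = _positive(
            "gastric_emptying_time",
            out.gastric_emptying_time * float(s["gastric_emptying_time"]))
    if "small_intestinal_transit_time" in s:
        out.small_intestinal_transit_time = _positive(
            "small_intestinal_transit_time",
            out.small_intestinal_transit_time * float(s["small_intestinal_transit_time"]))
    for enzyme, mult in dict(s.get("enzyme_activity", {})).items():
        out.enzyme_activity[enzyme] = _positive(
            f"enzyme_activity[{enzyme}]",
            out.enzyme_activity.get(enzyme, 1.0) * float(mult))
    return out.validate()


def population_to_frame(individuals: Sequence[IndividualPhysiology]):
    """Flatten a population to a pandas DataFrame (one row per individual)."""
    import pandas as pd

    rows = []
    for ind in individuals:
        row = {
            "subject_id": ind.subject_id, "sex": ind.sex, "age": ind.age,
            "body_weight": ind.body_weight, "hematocrit": ind.hematocrit,
            "GFR": ind.GFR, "binding_protein_scalar": ind.binding_protein_scalar,
            "gastric_emptying_time": ind.gastric_emptying_time,
            "small_intestinal_transit_time": ind.small_intestinal_transit_time,
            "cardiac_output": ind.cardiac_output,
            "hepatic_blood_flow_QH": ind.hepatic_blood_flow_QH,
            "stage": ind.stage,
        }
        row.update({f"V_{k}": v for k, v in ind.organ_volumes.items()})
        row.update({f"Q_{k}": v for k, v in ind.organ_blood_flows.items()})
        rows.append(row)
    return pd.DataFrame(rows)
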