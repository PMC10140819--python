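"""Hydroxychloroquine drug record and tissue partitioning.

Houses the drug-parameter record (shipped as ``data/hcq.yaml``), blood/plasma
bookkeeping, salt-to-base dose conversion, and mechanistic tissue:plasma
partition coefficients.

Partition schemes
-----------------
``rodgers_rowland`` (default)
    Composition-based scheme for ionised bases.  For a moderate-to-strong base
    (HCQ: diprotic, pKa 9.67/8.27) partitioning into tissue is dominated by
    electrostatic association with acidic phospholipids; the association
    constant is calibrated from the measured blood-cell partitioning implied
    by the whole-blood:plasma ratio, so the scheme reproduces B:P exactly.
``poulin_theil``
    Simpler lipid/water distribution alternative, selectable via the drug
    record's ``partition_scheme`` field.

Both schemes are pure functions of their inputs: identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping

import yaml

from .physiology import IndividualPhysiology, TISSUE_ORGANS

__all__ = [
    "DrugParameters",
    "PartitionSet",
    "DrugModelError",
    "load_drug",
    "fu_blood",
    "salt_to_base_dose",
    "compute_partition_set",
    "blood_cell_partition",
    "blood_plasma_ratio",
]


class DrugModelError(ValueError):
    """Invalid drug parameter or partitioning input."""


@dataclass
class DrugParameters:
    """Physicochemical/ADME record driving all simulation."""

    name: str
    molecular_weight: float           # g/mol
    logP: float
    pKa_values: List[float]           # basic pKas, most basic first
    fu_plasma: float                  # fraction unbound in plasma
    blood_to_plasma_ratio: float
    binding_partner: str              # 'AGP' | 'albumin'
    solubility_mg_per_ml: float
    solubility_pH: float
    intestinal_permeability_Peff: float   # cm/min
    renal_plasma_clearance_CLR: float     # L/h at reference GFR
    salt_to_base_factor: float = 0.775
    clearance: Dict = field(default_factory=dict)
    formulation: Dict = field(default_factory=dict)
    absorption: Dict = field(default_factory=dict)
    partition_scheme: str = "rodgers_rowland"
    adipose_oil_correction: bool = False
    reported_invitro_clearance: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> "DrugParameters":
        if self.molecular_weight <= 0:
            raise DrugModelError("molecular_weight must be > 0")
        if not 0.0 < self.fu_plasma <= 1.0:
            raise DrugModelError("fu_plasma must lie in (0,1]")
        if self.blood_to_plasma_ratio <= 0:
            raise DrugModelError("blood_to_plasma_ratio must be > 0")
        if self.renal_plasma_clearance_CLR < 0:
            raise DrugModelError("renal clearance must be >= 0")
        if self.intestinal_permeability_Peff < 0:
            raise DrugModelError("Peff must be >= 0")
        return self

    @classmethod
    def from_yaml(cls, path=None) -> "DrugParameters":
        """Load a drug record; ``path=None`` loads the shipped HCQ record."""
        if path is None:
            with resources.files("hcqpbpk.data").joinpath("hcq.yaml").open("r") as fh:
                raw = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_drug(path=None) -> DrugParameters:
    """Convenience wrapper for :meth:`DrugParameters.from_yaml`."""
    return DrugParameters.from_yaml(path)


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:plasma partition coefficients plus the blood unbound fraction."""

    kp: Mapping[str, float]           # organ -> Kp (tissue:plasma)
    fu_blood: float

    def validate(self) -> "PartitionSet":
        if not 0.0 < self.fu_blood <= 1.0:
            raise DrugModelError("fu_blood must lie in (0,1]")
        for organ, value in self.kp.items():
            if value <= 0:
                raise DrugModelError(f"Kp must be > 0 for organ {organ}")
        return self


def fu_blood(fu_plasma: float, bp_ratio: float) -> float:
    """Unbound fraction referenced to whole blood: ``fu / (B:P)``, capped at 1."""
    if bp_ratio <= 0:
        raise DrugModelError("blood:plasma ratio must be > 0")
    if not 0.0 < fu_plasma <= 1.0:
        raise DrugModelError("fu_plasma must lie in (0,1]")
    return min(1.0, fu_plasma / bp_ratio)


def salt_to_base_dose(dose_salt: float, factor: float = 0.775) -> float:
    """Convert an HCQ sulfate dose to free-base equivalents (200 mg -> 155 mg)."""
    if dose_salt < 0:
        raise DrugModelError("dose must be >= 0")
    return dose_salt * factor


def blood_cell_partition(bp_ratio: float, hematocrit: float, fu_plasma: float) -> float:
    """Unbound blood-cell:plasma-water partition Kpu_BC implied by B:P.

    From the identity B:P = (1 - H) + H * Kpu_BC * fu.
    """
    if not 0.0 < hematocrit < 1.0:
        raise DrugModelError("hematocrit must lie in (0,1)")
    kpu_bc = (bp_ratio - (1.0 - hematocrit)) / (hematocrit * fu_plasma)
    if kpu_bc <= 0:
        raise DrugModelError("B:P ratio inconsistent with hematocrit (Kpu_BC <= 0)")
    return kpu_bc


def blood_plasma_ratio(kpu_bc: float, hematocrit: float, fu_plasma: float) -> float:
    """Forward identity: whole-blood:plasma ratio from cell partitioning.

    Used to recompute B:P when disease alters hematocrit or plasma binding
    while the intrinsic cell affinity Kpu_BC is held at its healthy value.
    """
    return (1.0 - hematocrit) + hematocrit * kpu_bc * fu_plasma


def _ionisation(pkas: List[float], pH: float) -> float:
    """X = sum of ionised:neutral abundance ratios for a (di)protic base at pH."""
    if not pkas:
        return 0.0
    pkas = sorted(pkas, reverse=True)
    x = 10.0 ** (pkas[0] - pH)
    if len(pkas) > 1:
        x += 10.0 ** (pkas[0] + pkas[1] - 2.0 * pH)
    return x


def _load_composition() -> dict:
    with resources.files("hcqpbpk.data").joinpath("tissue_composition.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def compute_partition_set(
    drug: DrugParameters,
    physiology: IndividualPhysiology,
    scheme: str | None = None,
    fu_plasma: float | None = None,
    composition: Mapping | None = None,
) -> PartitionSet:
    """Mechanistic tissue:plasma partition coefficients for every organ.

    ``fu_plasma`` may be overridden (disease-adjusted binding); it defaults to
    the drug record's healthy value.  Raises if the shipped composition table
    lacks an organ present in the physiology.
    """
    scheme = scheme or drug.partition_scheme
    fu = drug.fu_plasma if fu_plasma is None else fu_plasma
    comp = composition if composition is not None else _load_composition()

    missing = [o for o in TISSUE_ORGANS if o not in comp["tissues"]]
    if missing:
        raise DrugModelError(f"tissue composition missing for organ(s): {missing}")

    if scheme == "rodgers_rowland":
        kp = _rodgers_rowland(drug, fu, comp)
    elif scheme == "poulin_theil":
        kp = _poulin_theil(drug, fu, comp)
    else:
        raise DrugModelError(f"unknown partition scheme {scheme!r}")
    return PartitionSet(kp=kp, fu_blood=fu_blood(fu, drug.blood_to_plasma_ratio)).validate()


def _rodgers_rowland(drug: DrugParameters, fu: float, comp: Mapping) -> Dict[str, float]:
    """Rodgers-Rowland Kp for an ionisable base (method for bases with pKa > pH).

    Kpu_T = f_ew + (1+X_iw)/(1+Y) f_iw + Ka [AP] X_iw/(1+Y)
            + (P f_nl + (0.3P+0.7) f_np)/(1+Y),         Kp = Kpu * fu

    X/Y are ionised:neutral ratios at intracellular/plasma pH.  The acidic-
    phospholipid association constant Ka is calibrated so the blood-cell
    compartment reproduces the measured B:P ratio; for neutral molecules the
    electrostatic term vanishes and the scheme reduces to lipid/water
    distribution.
    """
    pH_p = comp["pH_plasma"]
    pH_iw = comp["pH_intracellular"]
    pH_bc = comp["pH_blood_cell"]
    p_ow = 10.0 ** drug.logP
    x_iw = _ionisation(drug.pKa_values, pH_iw)
    y = _ionisation(drug.pKa_values, pH_p)

    def neutral_lipid_term(f_nl: float, f_np: float, p: float) -> float:
        return (p * f_nl + (0.3 * p + 0.7) * f_np) / (1.0 + y)

    ka = 0.0
    if x_iw > 0:
        bc = comp["blood_cells"]
        x_bc = _ionisation(drug.pKa_values, pH_bc)
        kpu_bc = blood_cell_partition(drug.blood_to_plasma_ratio,
                                      0.45, drug.fu_plasma)
        residual = (kpu_bc
                    - (1.0 + x_bc) / (1.0 + y) * bc["f_iw"]
                    - neutral_lipid_term(bc["f_nl"], bc["f_np"], p_ow))
        if residual <= 0:
            raise DrugModelError(
                "blood-cell partitioning inconsistent with composition table")
        ka = residual * (1.0 + y) / (bc["ap"] * x_bc)

    kp = {}
    for organ, t in comp["tissues"].items():
        p = p_ow
        if organ == "adipose" and drug.adipose_oil_correction:
            p = 10.0 ** (1.115 * drug.logP - 1.35)  # vegetable oil : water
        kpu = (t["f_ew"]
               + (1.0 + x_iw) / (1.0 + y) * t["f_iw"]
               + ka * t["ap"] * x_iw / (1.0 + y)
               + neutral_lipid_term(t["f_nl"], t["f_np"], p))
        kp[organ] = kpu * fu
    return kp


def _poulin_theil(drug: DrugParameters, fu: float, comp: Mapping) -> Dict[str, float]:
    """Poulin-Theil lipid/water Kp (non-ionised distribution alternative).

    Kp = [P(f_nl + 0.3 f_np) + (f_w + 0.7 f_np)] /
         [P(f_nl,p + 0.3 f_np,p) + (f_w,p + 0.7 f_np,p)] * fu/fu_t
    with plasma composition constants and fu_t estimated from fu assuming
    half the plasma binding capacity in tissue interstitium.
    """
    p_ow = 10.0 ** drug.logP
    f_nl_p, f_np_p, f_w_p = 0.0023, 0.0013, 0.945
    denom = p_ow * (f_nl_p + 0.3 * f_np_p) + (f_w_p + 0.7 * f_np_p)
    fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu) / fu)
    kp = {}
    for organ, t in comp["tissues"].items():
        p = p_ow
        if organ == "adipose" and drug.adipose_oil_correction:
            p = 10.0 ** (1.115 * drug.logP - 1.35)
        f_w = t["f_ew"] + t["f_iw"]
        num = p * (t["f_nl"] + 0.3 * t["f_np"]) + (f_w + 0.7 * t["f_np"])
        ratio = fu / fu_t if organ != "adipose" else fu  # adipose: fu_t ~ 1
        kp[organ] = num / denom * ratio
    return kp
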