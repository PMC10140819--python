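"""Hepatic and renal clearance terms for the PBPK model.

The central quantity is the hepatic intrinsic clearance CLint, back-calculated
from an observed hepatic blood clearance CLH with the well-stirred liver
model.  Two algebraic forms of the inversion are provided:

``as_printed`` (default)
    CLint = QH * CLH / (fuB * QH - CLH)

``standard_well_stirred``
    CLint = QH * CLH / (fuB * (QH - CLH))

The first mirrors the published back-calculation verbatim; the second is the
exact inverse of the forward well-stirred relation
CLH = QH * fuB * CLint / (QH + fuB * CLint).  For low-extraction drugs the two
are numerically close; both are exposed and logged.

CLint is apportioned to individual CYP enzymes by fractional contribution and
converted to in-vitro units (uL/min/pmol) through enzyme abundance; the
apportionment is conservative by construction (re-aggregation reproduces
CLint exactly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping

from .drug import DrugParameters, fu_blood
from .physiology import IndividualPhysiology

__all__ = [
    "ClearanceError",
    "ClearanceInputs",
    "ClearanceSet",
    "back_calculate_clint",
    "apportion_to_enzymes",
    "hepatic_clearance_term",
    "renal_clearance_scaled",
    "enzyme_abundance_pmol",
    "build_clearance_set",
    "explain_chain",
]

logger = logging.getLogger(__name__)

L_PER_H_TO_UL_PER_MIN = 1.0e6 / 60.0  # 1 L/h = 16666.7 uL/min


class ClearanceError(ValueError):
    """Inadmissible clearance inputs (e.g. CLH at or above unbound flow capacity)."""


@dataclass(frozen=True)
class ClearanceInputs:
    """Inputs to the back-calculation and apportionment chain."""

    QH: float                     # hepatic blood flow, L/h
    CLH: float                    # hepatic blood clearance, L/h
    fuB: float                    # unbound fraction in whole blood
    CLR_plasma: float             # renal plasma clearance, L/h
    enzyme_contributions: Mapping[str, float] = field(default_factory=dict)
    enzyme_abundance: Mapping[str, float] = field(default_factory=dict)  # pmol/liver

    def validate(self) -> "ClearanceInputs":
        if not self.QH > self.CLH >= 0:
            raise ClearanceError("require QH > CLH >= 0")
        if not 0.0 < self.fuB <= 1.0:
            raise ClearanceError("fuB must lie in (0,1]")
        if self.enzyme_contributions:
            total = sum(self.enzyme_contributions.values())
            if abs(total - 1.0) > 1e-9:
                raise ClearanceError(
                    f"enzyme contributions must sum to 1, got {total}")
        return self


@dataclass(frozen=True)
class ClearanceSet:
    """Clearance terms handed to the ODE engine for one individual."""

    CLint_total: float                         # L/h, whole liver
    per_enzyme_invitro: Mapping[str, float]    # enzyme -> uL/min/pmol
    renal_clearance_plasma: float              # L/h, GFR-scaled
    fuB: float


def back_calculate_clint(inputs: ClearanceInputs, form: str = "as_printed") -> float:
    """Back-calculate whole-liver intrinsic clearance (L/h) from CLH.

    Raises :class:`ClearanceError` when hepatic clearance exceeds unbound
    hepatic flow capacity (non-positive denominator).
    """
    inputs.validate()
    qh, clh, fub = inputs.QH, inputs.CLH, inputs.fuB
    if clh == 0:
        return 0.0
    if form == "as_printed":
        denom = fub * qh - clh
    elif form == "standard_well_stirred":
        denom = fub * (qh - clh)
    else:
        raise ClearanceError(f"unknown Eq-form {form!r}")
    if denom <= 0:
        raise ClearanceError(
            "hepatic clearance exceeds unbound hepatic flow capacity "
            f"(denominator {denom:.4g} <= 0 for form {form!r})")
    clint = qh * clh / denom
    logger.debug("back_calculate_clint[%s]: QH=%.4g CLH=%.4g fuB=%.4g -> CLint=%.6g L/h",
                 form, qh, clh, fub, clint)
    return clint


def hepatic_clearance_term(CLint: float, QH: float, fuB: float) -> float:
    """Forward well-stirred hepatic blood clearance (L/h), strictly < QH."""
    if CLint < 0 or QH <= 0 or not 0.0 < fuB <= 1.0:
        raise ClearanceError("require CLint >= 0, QH > 0, fuB in (0,1]")
    return QH * fuB * CLint / (QH + fuB * CLint)


def apportion_to_enzymes(
    CLint_total: float,
    contributions: Mapping[str, float],
    abundances: Mapping[str, float],
) -> Dict[str, float]:
    """Split whole-liver CLint into per-enzyme in-vitro clearances.

    value_e [uL/min/pmol] = CLint_total [L/h] * contribution_e
                            * (1e6/60) / abundance_e [pmol]

    Re-aggregation ``sum(value_e * abundance_e) * 60/1e6`` reproduces
    ``CLint_total`` exactly (conservation).
    """
    if set(contributions) != set(abundances):
        missing = set(contributions) ^ set(abundances)
        raise ClearanceError(f"enzyme mismatch between contributions and abundances: {missing}")
    total = sum(contributions.values())
    if abs(total - 1.0) > 1e-9:
        raise ClearanceError(f"contributions must sum to 1, got {total}")
    if any(a <= 0 for a in abundances.values()):
        raise ClearanceError("abundances must be > 0")
    return {
        e: CLint_total * contributions[e] * L_PER_H_TO_UL_PER_MIN / abundances[e]
        for e in contributions
    }


def reaggregate_clint(per_enzyme: Mapping[str, float],
                      abundances: Mapping[str, float]) -> float:
    """Inverse of :func:`apportion_to_enzymes`; returns whole-liver CLint in L/h."""
    return sum(per_enzyme[e] * abundances[e] for e in per_enzyme) / L_PER_H_TO_UL_PER_MIN


def renal_clearance_scaled(
    CLR_plasma_healthy: float,
    GFR_patient: float,
    GFR_reference: float,
) -> float:
    """Renal plasma clearance proportionally scaled with GFR (L/h)."""
    if GFR_patient <= 0 or GFR_reference <= 0:
        raise ClearanceError("GFR values must be > 0")
    return CLR_plasma_healthy * GFR_patient / GFR_reference


def enzyme_abundance_pmol(
    abundance_pmol_per_mg: Mapping[str, float],
    mppgl_mg_per_g: float,
    liver_volume_l: float,
    liver_density_g_per_ml: float = 1.05,
) -> Dict[str, float]:
    """Whole-liver enzyme amounts: pmol/mg protein x MPPGL x liver mass."""
    liver_g = liver_volume_l * 1000.0 * liver_density_g_per_ml
    return {e: a * mppgl_mg_per_g * liver_g for e, a in abundance_pmol_per_mg.items()}


def build_clearance_set(
    drug: DrugParameters,
    physiology: IndividualPhysiology,
    reference_physiology: IndividualPhysiology | None = None,
    form: str | None = None,
) -> ClearanceSet:
    """Assemble the individual's clearance terms from the drug record.

    The back-calculation is anchored at a healthy reference physiology
    (reference QH and liver volume; defaults to the sex-matched shipped
    reference so CLint is a drug-level constant, not an individual one); the
    individual's CLint then scales with relative liver volume and disease
    enzyme-activity multipliers, and the unbound blood fraction reflects
    disease-adjusted binding (fu_patient = fu_healthy / binding_protein_scalar,
    capped at 1).
    """
    from .physiology import table_reference

    cfg = drug.clearance
    ref = reference_physiology or table_reference(physiology.sex)
    form = form or cfg.get("eq_form", "as_printed")
    fu_ref = drug.fu_plasma
    fub_ref = fu_blood(fu_ref, drug.blood_to_plasma_ratio)

    inputs = ClearanceInputs(
        QH=ref.hepatic_blood_flow_QH,
        CLH=float(cfg["hepatic_blood_clearance"]),
        fuB=fub_ref,
        CLR_plasma=drug.renal_plasma_clearance_CLR,
        enzyme_contributions=cfg.get("enzyme_contributions", {}),
        enzyme_abundance=enzyme_abundance_pmol(
            cfg.get("enzyme_abundance_pmol_per_mg", {}),
            float(cfg.get("mppgl_mg_per_g", 40.0)),
            ref.organ_volumes["liver"],
            float(cfg.get("liver_density_g_per_ml", 1.05)),
        ),
    )
    clint_ref = back_calculate_clint(inputs, form=form) \
        * float(cfg.get("intrinsic_clearance_multiplier", 1.0))
    per_enzyme = (apportion_to_enzymes(clint_ref, dict(inputs.enzyme_contributions),
                                       dict(inputs.enzyme_abundance))
                  if inputs.enzyme_contributions else {})

    # individual scaling: liver size and per-enzyme disease activity
    size_scale = physiology.organ_volumes["liver"] / ref.organ_volumes["liver"]
    if inputs.enzyme_contributions:
        activity = sum(inputs.enzyme_contributions[e]
                       * physiology.enzyme_activity.get(e, 1.0)
                       for e in inputs.enzyme_contributions)
    else:
        activity = 1.0
    clint_ind = clint_ref * size_scale * activity

    # disease-adjusted binding
    fu_ind = min(1.0, fu_ref / physiology.binding_protein_scalar)
    from .drug import blood_cell_partition, blood_plasma_ratio
    kpu_bc = blood_cell_partition(drug.blood_to_plasma_ratio, 0.45, fu_ref)
    bp_ind = blood_plasma_ratio(kpu_bc, physiology.hematocrit, fu_ind)
    fub_ind = fu_blood(fu_ind, bp_ind)

    clr = renal_clearance_scaled(drug.renal_plasma_clearance_CLR,
                                 physiology.GFR, ref.GFR)
    return ClearanceSet(
        CLint_total=clint_ind,
        per_enzyme_invitro=per_enzyme,
        renal_clearance_plasma=clr,
        fuB=fub_ind,
    )


def explain_chain(drug: DrugParameters, physiology: IndividualPhysiology) -> str:
    """Human-readable back-calculation chain with units (CLI `clearance explain`)."""
    cfg = drug.clearance
    fub = fu_blood(drug.fu_plasma, drug.blood_to_plasma_ratio)
    qh = physiology.hepatic_blood_flow_QH
    clh = float(cfg["hepatic_blood_clearance"])
    lines = [
        "Well-stirred hepatic intrinsic clearance back-calculation",
        f"  fu(plasma)            = {drug.fu_plasma:.4g}",
        f"  B:P ratio             = {drug.blood_to_plasma_ratio:.4g}",
        f"  fuB = fu / (B:P)      = {fub:.4f}",
        f"  QH (hepatic blood flow) = {qh:.2f} L/h",
        f"  CLH (hepatic blood clearance) = {clh:.2f} L/h",
    ]
    for form in ("as_printed", "standard_well_stirred"):
        clint = back_calculate_clint(
            ClearanceInputs(QH=qh, CLH=clh, fuB=fub,
                            CLR_plasma=drug.renal_plasma_clearance_CLR),
            form=form)
        lines.append(f"  CLint [{form}] = {clint:.3f} L/h")
        if cfg.get("enzyme_contributions"):
            ab = enzyme_abundance_pmol(
                cfg["enzyme_abundance_pmol_per_mg"],
                float(cfg.get("mppgl_mg_per_g", 40.0)),
                physiology.organ_volumes["liver"],
                float(cfg.get("liver_density_g_per_ml", 1.05)))
            per = apportion_to_enzymes(clint, cfg["enzyme_contributions"], ab)
            for e in sorted(per):
                lines.append(
                    f"    {e}: contribution {cfg['enzyme_contributions'][e]:.2f}, "
                    f"abundance {ab[e]:.3g} pmol -> {per[e]:.4g} uL/min/pmol")
    lines.append(
        f"  Renal plasma clearance = {drug.renal_plasma_clearance_CLR:.3g} L/h "
        f"(scaled by GFR {physiology.GFR:.0f}/reference)")
    return "\n".join(lines)
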