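"""Pseudo-observed concentration-time datasets.

The clinical HCQ profiles behind the model evaluation were digitised from
1988-2012 publications and are not redistributable; this module generates
structurally matched stand-ins so the whole pipeline (simulate -> NCA ->
R-ratio qualification) is testable end to end.  A fixture registry mirrors
the study designs (routes, doses, infusion time, demographics); pseudo-
observations are engine simulations under log-normally perturbed drug
parameters, sampled on sparse clinical-style grids with proportional +
additive residual noise.  Everything is seeded and returns the ground truth
alongside the noisy data, enabling recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .drug import DrugParameters
from .engine import DosingRegimen, ConcentrationTimeProfile, PBPKModel
from .nca import run_nca, NCAResult
from .physiology import build_reference_adult

__all__ = [
    "StudyFixture",
    "NoiseModel",
    "make_fixture_registry",
    "generate_pseudo_observed",
    "split_development_verification",
]

# sparse clinical-style sampling grids (h): dense early, sparse late
_IV_GRID = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0,
            24.0, 36.0, 48.0, 72.0)
_ORAL_GRID = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0,
              72.0, 96.0, 120.0)


@dataclass(frozen=True)
class StudyFixture:
    """Design metadata of one source clinical study."""

    study_id: str
    route: str                     # 'iv_infusion' | 'oral'
    dose: float                    # mg as published (base, or salt if flagged)
    n_subjects: int
    female_fraction: float
    mean_age: float                # years
    mean_weight: float             # kg
    infusion_duration: float | None = None   # min, IV only
    sampling_grid: Tuple[float, ...] = ()    # h
    dose_is_salt: bool = False     # 200 mg sulfate label doses

    @property
    def dose_base(self) -> float:
        from .drug import salt_to_base_dose

        return salt_to_base_dose(self.dose) if self.dose_is_salt else self.dose

    def regimen(self) -> DosingRegimen:
        if self.route == "iv_infusion":
            return DosingRegimen(route="iv_infusion", dose_base=self.dose_base,
                                 infusion_duration=self.infusion_duration or 30.0)
        return DosingRegimen(route="oral", dose_base=self.dose_base)


@dataclass(frozen=True)
class NoiseModel:
    """Residual + parameter noise emulating digitisation and biology."""

    proportional_cv: float = 0.15
    additive_sd: float = 0.0          # ng/mL
    parameter_perturbation_cv: float = 0.0
    seed: int = 0

    def validate(self) -> "NoiseModel":
        if min(self.proportional_cv, self.additive_sd,
               self.parameter_perturbation_cv) < 0:
            raise ValueError("noise magnitudes must be >= 0")
        return self


def make_fixture_registry() -> List[StudyFixture]:
    """The eight study fixtures behind the healthy-model evaluation.

    Three IV-infusion entries (Tett 1988/1989/1992; the 1988 study also ran a
    155 mg arm, and the oral crossover studies contribute per-volunteer and
    per-week profiles — the expansion from 8 study entries to 12 disposition
    profiles happens at evaluation time, not here).  All IV infusions last
    30 min; the Tett doses (155/310 mg) are free base, while the 200 mg
    tablet studies carry their published sulfate label dose and convert to
    155 mg base when the regimen is built.
    """
    return [
        StudyFixture("iv_tett_1988", "iv_infusion", 310.0, 5, 0.60, 22.6, 63.5,
                     infusion_duration=30.0, sampling_grid=_IV_GRID),
        StudyFixture("iv_tett_1989", "iv_infusion", 155.0, 5, 0.60, 22.6, 63.5,
                     infusion_duration=30.0, sampling_grid=_IV_GRID),
        StudyFixture("iv_tett_1992", "iv_infusion", 155.0, 9, 0.66, 24.4, 71.4,
                     infusion_duration=30.0, sampling_grid=_IV_GRID),
        StudyFixture("oral_williams_1988", "oral", 310.0, 2, 0.5, 30.0, 84.0,
                     sampling_grid=_ORAL_GRID),
        StudyFixture("oral_tett_1989", "oral", 155.0, 5, 0.60, 22.6, 63.5,
                     sampling_grid=_ORAL_GRID),
        StudyFixture("oral_tett_1992", "oral", 155.0, 9, 0.66, 24.4, 71.4,
                     sampling_grid=_ORAL_GRID),
        StudyFixture("oral_ducharme_1995", "oral", 200.0, 24, 0.0, 28.0, 80.0,
                     sampling_grid=_ORAL_GRID, dose_is_salt=True),
        StudyFixture("oral_liu_2012", "oral", 200.0, 27, 0.0, 25.0, 63.0,
                     sampling_grid=_ORAL_GRID, dose_is_salt=True),
    ]


def _perturbed_drug(drug: DrugParameters, cv: float,
                    rng: np.random.Generator) -> DrugParameters:
    """Log-normally perturb the disposition-determining parameters."""
    import copy

    if cv == 0:
        return drug
    sigma = np.sqrt(np.log1p(cv * cv))

    def factor() -> float:
        return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))

    out = copy.deepcopy(drug)
    out.clearance = dict(out.clearance)
    # perturb the forward-direction parameters only: intrinsic clearance can
    # take any positive multiplier without breaking the back-calculation
    out.clearance["intrinsic_clearance_multiplier"] = \
        float(out.clearance.get("intrinsic_clearance_multiplier", 1.0)) * factor()
    out.renal_plasma_clearance_CLR *= factor()
    # distribution perturbation through lipophilicity (shifts every Kp)
    out.logP += rng.normal(0.0, cv)
    return out


def generate_pseudo_observed(
    fixture: StudyFixture,
    truth_drug: DrugParameters,
    noise: NoiseModel,
) -> Tuple[ConcentrationTimeProfile, Dict]:
    """Simulate one pseudo-observed dataset plus its ground-truth record.

    Returns ``(noisy_profile, truth)`` where ``truth`` holds the perturbed
    drug record, the noise-free profile on the fixture grid, and its NCA.
    Identical ``noise.seed`` gives identical output; zero noise and zero
    perturbation return the engine's simulation exactly.
    """
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    drug = _perturbed_drug(truth_drug, noise.parameter_perturbation_cv, rng)
    subject = build_reference_adult(
        "F" if fixture.female_fraction >= 0.5 else "M",
        min(max(fixture.mean_age, 18.0), 65.0),
        fixture.mean_weight,
        subject_id=fixture.study_id)
    grid = np.array((0.0,) + tuple(fixture.sampling_grid))
    sim = PBPKModel(subject, drug, fixture.regimen()).simulate(times=grid)
    clean = sim.profile.concentration

    prop = 1.0 + noise.proportional_cv * rng.standard_normal(clean.size)
    add = noise.additive_sd * rng.standard_normal(clean.size)
    noisy = np.clip(clean * prop + add, 0.0, None)
    profile = ConcentrationTimeProfile(
        times=grid, concentration=noisy, matrix="blood",
        subject_id=fixture.study_id, regimen=fixture.regimen()).validate()
    truth = {
        "drug": drug,
        "clean_profile": sim.profile,
        "nca": run_nca(sim.profile, fixture.regimen().dose_base),
    }
    return profile, truth


def split_development_verification(
    fixtures: Sequence[StudyFixture],
) -> Tuple[List[StudyFixture], List[StudyFixture]]:
    """Deterministic development/verification split by registry order.

    Development: the first IV and first two oral fixtures (1 IV + 2 oral);
    verification: the remaining 2 IV + 3 oral.  Which specific studies formed
    the source development third is not identified beyond route counts, so
    registry order is the documented convention.
    """
    iv = [f for f in fixtures if f.route == "iv_infusion"]
    oral = [f for f in fixtures if f.route == "oral"]
    dev = iv[:1] + oral[:2]
    verification = iv[1:] + oral[2:]
    return dev, verification
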