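"""Whole-body perfusion-limited PBPK ODE engine.

The body is a closed loop of perfusion-limited (flow-limited) organ
compartments: venous blood -> lung -> arterial blood -> tissues -> venous
blood, with gut and spleen draining through the liver (portal vein).  Each
organ obeys a mass balance

    dA_T/dt = Q_T * (C_in - C_T / Kpb_T)            [amounts in mg]

where ``Kpb_T = Kp_T / (B:P)`` is the tissue:blood partition coefficient, so
``C_T / Kpb_T`` is the emergent venous *blood* concentration of the organ.
Elimination follows the well-stirred convention: hepatic metabolism removes
``CLint * fuB * C_out,liver`` and renal excretion ``CLR_blood * C_out,kidney``
(CLR_blood = GFR-scaled plasma clearance / B:P).

Dosing
------
IV: zero-order infusion into venous blood over the infusion duration.
Oral: the formulation releases drug linearly (Lint80: 80% over the dissolution
time, after a lag; by default the same rate continues to 100%).  Dissolved
drug empties from the stomach (first order, 1/GET), is absorbed from a single
small-intestine compartment (first order, ka = Peff x effective area / lumen
volume) into the portal inflow of the liver (first pass), or lost distally
(first order, 1/SITT).

Every milligram is tracked: cumulative metabolised, renally excreted, and
transit-lost amounts are states, so mass balance is auditable at any time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .clearance import ClearanceSet, build_clearance_set
from .drug import (DrugParameters, PartitionSet, blood_cell_partition,
                   blood_plasma_ratio, compute_partition_set)
from .physiology import (ARTERIAL_ORGANS, IndividualPhysiology, TISSUE_ORGANS)

__all__ = [
    "DosingRegimen",
    "ConcentrationTimeProfile",
    "EngineError",
    "lint80_release_fraction",
    "PBPKModel",
    "SimulationResult",
    "default_time_grid",
]


class EngineError(ValueError):
    """Engine assembly or integration failure."""


def default_time_grid(t_end: float = 72.0, dt: float = 0.1) -> np.ndarray:
    """Default output grid in hours (0 to t_end inclusive)."""
    n = int(round(t_end / dt))
    return np.linspace(0.0, t_end, n + 1)


@dataclass(frozen=True)
class DosingRegimen:
    """Route, dose (free base, mg), and formulation/infusion timing."""

    route: str                       # 'iv_infusion' | 'oral'
    dose_base: float                 # mg free base
    infusion_duration: float = 30.0  # min, IV only
    release_model: str = "lint80"
    dissolution_time: float = 300.0  # min to 80% released (after lag)
    lag_time: float = 60.0           # min
    cap_release_at_80pct: bool = False
    times: np.ndarray | None = None  # output grid, h

    def validate(self) -> "DosingRegimen":
        if self.route not in ("iv_infusion", "oral"):
            raise EngineError(f"unknown route {self.route!r}")
        if self.dose_base <= 0:
            raise EngineError("dose_base must be > 0")
        if self.route == "iv_infusion" and self.infusion_duration <= 0:
            raise EngineError("infusion_duration must be > 0 for IV")
        if self.route == "oral":
            if self.release_model != "lint80":
                raise EngineError(f"unknown release model {self.release_model!r}")
            if self.dissolution_time <= 0 or self.lag_time < 0:
                raise EngineError("need dissolution_time > 0 and lag_time >= 0")
        return self


@dataclass
class ConcentrationTimeProfile:
    """Whole-blood (or plasma) concentration series for one subject."""

    times: np.ndarray                # h
    concentration: np.ndarray        # ng/mL
    matrix: str = "blood"            # 'blood' | 'plasma'
    subject_id: str = "ref"
    regimen: DosingRegimen | None = None

    def validate(self) -> "ConcentrationTimeProfile":
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise EngineError("times and concentration must be 1-D and congruent")
        if np.any(np.diff(t) <= 0):
            raise EngineError("times must be strictly increasing")
        if np.any(c < 0):
            raise EngineError("concentrations must be >= 0")
        if self.matrix not in ("blood", "plasma"):
            raise EngineError(f"unknown matrix {self.matrix!r}")
        self.times, self.concentration = t, c
        return self

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.times,
            "conc_ng_per_ml": self.concentration,
            "matrix": self.matrix,
            "subject_id": self.subject_id,
        })


def lint80_release_fraction(t: float | np.ndarray, dissolution_time: float,
                            lag_time: float, cap_at_80pct: bool = False):
    """Cumulative Lint80 released fraction at time t (minutes).

    Zero until the lag, then linear with slope 0.80/dissolution_time.  By
    default the same linear rate continues past 80% up to complete release;
    with ``cap_at_80pct`` the profile truncates at 0.80.
    """
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - lag_time) * 0.80 / dissolution_time, 0.0,
                   0.80 if cap_at_80pct else 1.0)
    return float(frac) if frac.ndim == 0 else frac


# state vector layout
_N_ORGANS = len(TISSUE_ORGANS)
_I_ART = _N_ORGANS
_I_VEN = _N_ORGANS + 1
_I_SOLID = _N_ORGANS + 2
_I_STOMACH = _N_ORGANS + 3
_I_INTESTINE = _N_ORGANS + 4
_I_TRANSIT = _N_ORGANS + 5
_I_MET = _N_ORGANS + 6
_I_RENAL = _N_ORGANS + 7
_N_STATES = _N_ORGANS + 8

STATE_NAMES = list(TISSUE_ORGANS) + [
    "arterial_blood", "venous_blood", "lumen_undissolved", "lumen_stomach",
    "lumen_intestine", "transit_lost", "metabolized", "renal_excreted",
]


@dataclass
class SimulationResult:
    """Integrated trajectories plus the observable blood profile."""

    model: "PBPKModel"
    times: np.ndarray                   # h
    states: np.ndarray                  # (n_states, n_times), mg
    profile: ConcentrationTimeProfile

    def amount(self, name: str) -> np.ndarray:
        return self.states[STATE_NAMES.index(name)]

    def total_in_system(self) -> np.ndarray:
        """All drug accounted for (body + GI lumen + eliminated), mg."""
        return self.states.sum(axis=0)

    def dose_delivered(self) -> np.ndarray:
        """Cumulative drug introduced into the system at each time, mg."""
        m = self.model
        if m.regimen.route == "oral":
            return np.full_like(self.times, m.regimen.dose_base)
        tau = m.regimen.infusion_duration / 60.0
        return m.regimen.dose_base * np.clip(self.times / tau, 0.0, 1.0)

    def mass_balance_error(self) -> float:
        """Max |total - delivered| / dose, over the simulated horizon."""
        dev = np.abs(self.total_in_system() - self.dose_delivered())
        return float(dev.max() / self.model.regimen.dose_base)

    def plasma_profile(self) -> ConcentrationTimeProfile:
        """Blood concentrations converted to plasma via the individual B:P."""
        return ConcentrationTimeProfile(
            times=self.profile.times,
            concentration=self.profile.concentration / self.model.bp_ratio,
            matrix="plasma",
            subject_id=self.profile.subject_id,
            regimen=self.model.regimen,
        ).validate()


class PBPKModel:
    """Assembled whole-body PBPK system for one individual and one regimen.

    Partition coefficients and clearance terms default to being derived from
    the drug record with disease-adjusted binding (fu/binding_protein_scalar)
    and the individual's hematocrit; pass explicit ``partitions``/``clearances``
    to override.
    """

    def __init__(
        self,
        individual: IndividualPhysiology,
        drug: DrugParameters,
        regimen: DosingRegimen,
        partitions: PartitionSet | None = None,
        clearances: ClearanceSet | None = None,
        reference: IndividualPhysiology | None = None,
    ):
        self.individual = individual.validate()
        self.drug = drug.validate()
        self.regimen = regimen.validate()
        ref = reference  # None -> sex-matched table reference in build_clearance_set

        fu_ind = min(1.0, drug.fu_plasma / individual.binding_protein_scalar)
        kpu_bc = blood_cell_partition(drug.blood_to_plasma_ratio, 0.45, drug.fu_plasma)
        self.bp_ratio = blood_plasma_ratio(kpu_bc, individual.hematocrit, fu_ind)
        self.partitions = partitions if partitions is not None else \
            compute_partition_set(drug, individual, fu_plasma=fu_ind)
        self.clearances = clearances if clearances is not None else \
            build_clearance_set(drug, individual, reference_physiology=ref)

        missing = [o for o in TISSUE_ORGANS if o not in self.partitions.kp]
        if missing:
            raise EngineError(f"partition set lacks organ(s): {missing}")

        # cached arrays for the RHS
        ind = self.individual
        self._V = np.array([ind.organ_volumes[o] for o in TISSUE_ORGANS])
        self._V_art = ind.organ_volumes["arterial_blood"]
        self._V_ven = ind.organ_volumes["venous_blood"]
        self._Q = {o: ind.organ_blood_flows[o] for o in ARTERIAL_ORGANS}
        self._CO = ind.cardiac_output
        self._QH = ind.hepatic_blood_flow_QH
        self._kpb = np.array([self.partitions.kp[o] / self.bp_ratio
                              for o in TISSUE_ORGANS])
        self._idx = {o: i for i, o in enumerate(TISSUE_ORGANS)}
        # non-splanchnic organs draining directly into venous blood
        self._direct = [o for o in ARTERIAL_ORGANS if o not in ("liver", "gut", "spleen")]
        self._Q_direct = np.array([self._Q[o] for o in self._direct])
        self._i_direct = np.array([self._idx[o] for o in self._direct])
        self._clint_fub = self.clearances.CLint_total * self.clearances.fuB
        self._clr_blood = self.clearances.renal_clearance_plasma / self.bp_ratio

        # oral absorption constants (1/h)
        ab = drug.absorption or {}
        area = float(ab.get("smooth_surface_area_cm2", 2200.0))
        amp = float(ab.get("mucosal_amplification", 240.0))
        vlum = float(ab.get("lumen_volume_ml", 350.0))
        self._ka = drug.intestinal_permeability_Peff * area * amp / vlum * 60.0
        self._kge = 60.0 / ind.gastric_emptying_time
        self._ktr = 60.0 / ind.small_intestinal_transit_time

    # -- dosing inputs -----------------------------------------------------

    def _infusion_rate(self, t: float) -> float:
        tau = self.regimen.infusion_duration / 60.0
        return self.regimen.dose_base / tau if 0.0 <= t < tau else 0.0

    def _release_rate(self, t: float) -> float:
        r = self.regimen
        lag_h = r.lag_time / 60.0
        slope = 0.80 / (r.dissolution_time / 60.0)      # fraction per h
        f_end = 0.80 if r.cap_release_at_80pct else 1.0
        t_end = lag_h + f_end / slope
        return r.dose_base * slope if lag_h <= t < t_end else 0.0

    def _breakpoints(self) -> list[float]:
        r = self.regimen
        if r.route == "iv_infusion":
            return [r.infusion_duration / 60.0]
        lag_h = r.lag_time / 60.0
        slope = 0.80 / (r.dissolution_time / 60.0)
        f_end = 0.80 if r.cap_release_at_80pct else 1.0
        return [lag_h, lag_h + f_end / slope]

    # -- ODE right-hand side ----------------------------------------------

    def _rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(_N_STATES)
        ct_out = y[:_N_ORGANS] / self._V / self._kpb   # organ venous-blood conc
        c_art = y[_I_ART] / self._V_art
        c_ven = y[_I_VEN] / self._V_ven
        idx = self._idx

        # uptake from arterial blood for every arterially perfused organ
        for o in ARTERIAL_ORGANS:
            i = idx[o]
            dy[i] = self._Q[o] * (c_art - ct_out[i])
        # lung sits in series carrying all venous return
        i_lung = idx["lung"]
        dy[i_lung] = self._CO * (c_ven - ct_out[i_lung])
        dy[_I_ART] = self._CO * (ct_out[i_lung] - c_art)

        # portal chain: gut + spleen outflow re-enters the liver
        portal = (self._Q["gut"] * ct_out[idx["gut"]]
                  + self._Q["spleen"] * ct_out[idx["spleen"]])
        i_liv = idx["liver"]
        # liver balance: replace its simple arterial term with the full one
        hepatic_out = self._QH * ct_out[i_liv]
        metabolised = self._clint_fub * ct_out[i_liv]
        dy[i_liv] = (self._Q["liver"] * c_art + portal - hepatic_out - metabolised)
        # gut and spleen already have (C_art - C_out) terms: correct, their
        # outflow goes portally, not to venous blood.

        renal = self._clr_blood * ct_out[idx["kidney"]]
        dy[idx["kidney"]] -= renal

        dy[_I_VEN] = (np.dot(self._Q_direct, ct_out[self._i_direct])
                      + hepatic_out - self._CO * c_ven)
        dy[_I_MET] = metabolised
        dy[_I_RENAL] = renal

        if self.regimen.route == "iv_infusion":
            dy[_I_VEN] += self._infusion_rate(t)
        else:
            release = self._release_rate(t)
            dy[_I_SOLID] = -release
            dy[_I_STOMACH] = release - self._kge * y[_I_STOMACH]
            absorbed = self._ka * y[_I_INTESTINE]
            lost = self._ktr * y[_I_INTESTINE]
            dy[_I_INTESTINE] = self._kge * y[_I_STOMACH] - absorbed - lost
            dy[_I_TRANSIT] = lost
            dy[i_liv] += absorbed
        return dy

    # -- integration -------------------------------------------------------

    def simulate(
        self,
        times: np.ndarray | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        method: str = "LSODA",
    ) -> SimulationResult:
        """Integrate the system and return the whole-blood profile (ng/mL).

        Integration proceeds piecewise between dosing discontinuities
        (infusion end; release lag/end) so the stiff solver never steps over
        a corner.
        """
        r = self.regimen
        if times is None:
            times = r.times if r.times is not None else default_time_grid()
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise EngineError("output times must be 1-D strictly increasing")

        y0 = np.zeros(_N_STATES)
        if r.route == "oral":
            y0[_I_SOLID] = r.dose_base

        t0 = float(times[0])
        t_end = float(times[-1])
        bps = sorted({b for b in self._breakpoints() if t0 < b < t_end})
        edges = [t0, *bps, t_end]

        out = np.empty((_N_STATES, times.size))
        filled = 0
        y = y0.copy()
        for a, b in zip(edges[:-1], edges[1:]):
            mask = (times >= a) & (times <= b) if b == t_end else \
                   (times >= a) & (times < b)
            t_eval = times[mask]
            sol = solve_ivp(self._rhs, (a, b), y, method=method,
                            t_eval=t_eval if t_eval.size else None,
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise EngineError(f"ODE integration failed on [{a:.3g},{b:.3g}] h: "
                                  f"{sol.message}")
            if t_eval.size:
                out[:, filled:filled + t_eval.size] = sol.y
                filled += t_eval.size
            y = sol.y[:, -1] if sol.t[-1] == b else sol.y[:, -1]
            if sol.t[-1] != b:   # t_eval may stop short of the segment edge
                sol2 = solve_ivp(self._rhs, (sol.t[-1], b), y, method=method,
                                 rtol=rtol, atol=atol)
                if not sol2.success:
                    raise EngineError(f"ODE integration failed: {sol2.message}")
                y = sol2.y[:, -1]
        if filled != times.size:
            raise EngineError("internal error: output grid not fully covered")

        conc = out[_I_VEN] / self._V_ven * 1000.0     # mg/L -> ng/mL
        conc = np.where(conc < 0, np.where(conc > -1e-9, 0.0, conc), conc)
        profile = ConcentrationTimeProfile(
            times=times, concentration=conc, matrix="blood",
            subject_id=self.individual.subject_id, regimen=r).validate()
        return SimulationResult(model=self, times=times, states=out, profile=profile)


def simulate_individual(
    individual: IndividualPhysiology,
    drug: DrugParameters,
    regimen: DosingRegimen,
    reference: IndividualPhysiology | None = None,
    times: np.ndarray | None = None,
    **kwargs,
) -> SimulationResult:
    """One-call convenience: assemble the model and integrate."""
    return PBPKModel(individual, drug, regimen, reference=reference).simulate(
        times=times, **kwargs)
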