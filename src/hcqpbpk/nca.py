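"""Non-compartmental analysis and model-qualification machinery.

Implements the evaluation layer used to qualify the PBPK predictions:

* NCA metrics (Cmax, Tmax, AUC0-t by linear trapezoid, terminal log-linear
  rate, AUC0-inf, CL = Dose/AUC0-inf);
* observed/predicted R ratios and the 2-fold acceptance rule
  (R in [1/fold, fold], boundaries inclusive);
* visual-predictive-check envelopes (pointwise mean/min/max and 5th-95th
  percentiles, linear-interpolation percentile definition);
* population AUC summaries (median with seeded percentile-bootstrap 95% CI);
* percent change of a disease median versus healthy.

CL is defined as Dose/AUC0-inf: published observed CL values are inconsistent
with Dose/AUC0-t for truncated sampling of a drug with a multi-week terminal
phase, whereas extrapolated AUC reproduces them to NCA convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .engine import ConcentrationTimeProfile

__all__ = [
    "NCAError",
    "NCAResult",
    "EvaluationRecord",
    "PopulationSummary",
    "run_nca",
    "ratio",
    "within_fold",
    "vpc_envelope",
    "summarize_population_auc",
    "percent_change",
    "load_printed_evaluation",
    "load_reported_medians",
    "evaluate_pairs",
]

MG_TO_NG = 1.0e6
ML_TO_L = 1.0e-3


class NCAError(ValueError):
    """Invalid profile or evaluation input."""


@dataclass
class NCAResult:
    """Model-free PK metrics of one concentration-time profile."""

    Cmax: float                    # ng/mL
    Tmax: float                    # h
    AUC0_t: float                  # ng.h/mL
    AUC0_inf: float | None         # ng.h/mL (None if terminal fit failed)
    terminal_rate: float | None    # 1/h
    CL: float | None               # L/h, Dose/AUC0_inf
    extrapolated_fraction: float | None
    flagged: bool = False          # True when the terminal phase could not be fit


def run_nca(profile: ConcentrationTimeProfile, dose_base: float,
            n_terminal: int = 3) -> NCAResult:
    """Non-compartmental analysis of a sampled profile.

    AUC0-t is the linear trapezoid on the sampled grid.  The terminal rate is
    a log-linear regression over the last ``n_terminal`` strictly positive
    samples; a non-positive slope flags the result (AUC0-inf/CL unset) rather
    than raising.
    """
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentration, dtype=float)
    if t.size < 3:
        raise NCAError("need at least 3 time points for NCA")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly increasing")
    if n_terminal < 2:
        raise NCAError("terminal fit needs at least 2 points")

    auc0t = float(np.trapezoid(c, t))
    if auc0t <= 0:
        raise NCAError("AUC0-t must be positive")
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])

    pos = np.flatnonzero(c > 0)
    result = NCAResult(Cmax=cmax, Tmax=tmax, AUC0_t=auc0t, AUC0_inf=None,
                       terminal_rate=None, CL=None, extrapolated_fraction=None,
                       flagged=True)
    if pos.size < n_terminal:
        return result
    tail = pos[-n_terminal:]
    slope, _ = np.polyfit(t[tail], np.log(c[tail]), 1)
    if slope >= 0:
        return result
    lam = -float(slope)
    c_last = float(c[pos[-1]])
    auc_inf = auc0t + c_last / lam
    # CL: dose mg -> ng, AUC ng.h/mL -> CL mL/h -> L/h
    cl = dose_base * MG_TO_NG / auc_inf * ML_TO_L
    result.AUC0_inf = auc_inf
    result.terminal_rate = lam
    result.CL = cl
    result.extrapolated_fraction = (auc_inf - auc0t) / auc_inf
    result.flagged = False
    return result


def ratio(observed: float, predicted: float) -> float:
    """Observed/predicted R ratio (full precision; display rounds to 2 d.p.)."""
    if predicted <= 0:
        raise NCAError("predicted value must be > 0")
    return observed / predicted


def within_fold(r: float, fold: float = 2.0) -> bool:
    """True iff the ratio lies in [1/fold, fold], boundaries inclusive."""
    if fold <= 1:
        raise NCAError("fold must be > 1")
    if r <= 0:
        raise NCAError("ratio must be > 0")
    return 1.0 / fold <= r <= fold


@dataclass
class EvaluationRecord:
    """One observed/predicted pair with its R ratio and 2-fold verdict."""

    study_id: str
    parameter: str                # 'Cmax' | 'AUC0_t' | 'CL'
    observed: float
    predicted: float
    ratio: float
    within_2fold: bool


def evaluate_pairs(pairs: Sequence[tuple[str, str, float, float]],
                   fold: float = 2.0) -> List[EvaluationRecord]:
    """Build evaluation records from (study_id, parameter, obs, pred) tuples."""
    out = []
    for study_id, parameter, obs, pred in pairs:
        r = ratio(obs, pred)
        out.append(EvaluationRecord(study_id=study_id, parameter=parameter,
                                    observed=obs, predicted=pred, ratio=r,
                                    within_2fold=within_fold(r, fold)))
    return out


@dataclass
class PopulationSummary:
    """Population AUC summary plus VPC envelope curves."""

    stage: str
    route: str
    n: int
    median_AUC0_t: float
    ci95_low: float
    ci95_high: float
    p5_AUC0_t: float
    p95_AUC0_t: float
    times: np.ndarray | None = None          # VPC grid, h
    mean_curve: np.ndarray | None = None     # ng/mL
    min_curve: np.ndarray | None = None
    max_curve: np.ndarray | None = None
    p5_curve: np.ndarray | None = None
    p95_curve: np.ndarray | None = None

    def validate(self) -> "PopulationSummary":
        if not self.ci95_low <= self.median_AUC0_t <= self.ci95_high:
            raise NCAError("median must lie within its CI")
        return self


def vpc_envelope(profiles: Sequence[ConcentrationTimeProfile]) -> Dict[str, np.ndarray]:
    """Pointwise mean/min/max and 5th/95th percentile curves on a common grid.

    Percentiles use the linear-interpolation definition (numpy default,
    'type 7'): for n sorted values the p-th percentile interpolates at rank
    1 + (n-1)p/100.  Mismatched grids raise; resampling is the caller's job.
    """
    if len(profiles) < 2:
        raise NCAError("VPC needs at least 2 profiles")
    t0 = np.asarray(profiles[0].times, dtype=float)
    mat = []
    for p in profiles:
        t = np.asarray(p.times, dtype=float)
        if t.shape != t0.shape or not np.allclose(t, t0):
            raise NCAError("profiles must share a common time grid")
        mat.append(np.asarray(p.concentration, dtype=float))
    mat = np.vstack(mat)
    return {
        "times": t0,
        "mean": mat.mean(axis=0),
        "min": mat.min(axis=0),
        "max": mat.max(axis=0),
        "p5": np.percentile(mat, 5, axis=0),
        "p95": np.percentile(mat, 95, axis=0),
    }


def summarize_population_auc(
    nca_results: Sequence[NCAResult],
    stage: str,
    route: str,
    n_boot: int = 1000,
    seed: int = 0,
    envelope: Dict[str, np.ndarray] | None = None,
) -> PopulationSummary:
    """Median AUC0-t with a seeded percentile-bootstrap 95% CI.

    The CI method is a documented package choice (percentile bootstrap of the
    median, ``n_boot`` resamples); the source analyses do not state one.
    """
    aucs = np.array([r.AUC0_t for r in nca_results], dtype=float)
    if aucs.size < 10:
        raise NCAError("population summary needs >= 10 NCA results")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, aucs.size, size=(n_boot, aucs.size))
    boot_medians = np.median(aucs[idx], axis=1)
    lo, hi = np.percentile(boot_medians, [2.5, 97.5])
    median = float(np.median(aucs))
    extra = {}
    if envelope is not None:
        extra = {"times": envelope["times"], "mean_curve": envelope["mean"],
                 "min_curve": envelope["min"], "max_curve": envelope["max"],
                 "p5_curve": envelope["p5"], "p95_curve": envelope["p95"]}
    return PopulationSummary(
        stage=stage, route=route, n=int(aucs.size),
        median_AUC0_t=median, ci95_low=float(min(lo, median)),
        ci95_high=float(max(hi, median)),
        p5_AUC0_t=float(np.percentile(aucs, 5)),
        p95_AUC0_t=float(np.percentile(aucs, 95)),
        **extra,
    ).validate()


def percent_change(healthy_median: float, disease_median: float) -> float:
    """Percent change of a disease median vs healthy (positive = increase)."""
    if healthy_median <= 0:
        raise NCAError("healthy median must be > 0")
    return 100.0 * (disease_median - healthy_median) / healthy_median


def load_printed_evaluation() -> pd.DataFrame:
    """Published healthy-model evaluation table (observed, predicted, R)."""
    with resources.files("hcqpbpk.data").joinpath(
            "healthy_evaluation_table.csv").open("r") as fh:
        return pd.read_csv(fh)


def load_reported_medians() -> dict:
    """Published population AUC0-t medians (healthy/cirrhosis/CKD, both routes)."""
    import yaml

    with resources.files("hcqpbpk.data").joinpath(
            "reported_disease_medians.yaml").open("r") as fh:
        return yaml.safe_load(fh)
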