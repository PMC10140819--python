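"""Orchestration: healthy -> disease population pipeline and reporting.

``run_pipeline`` executes, from a single :class:`RunConfig`:

    population build -> disease scaling -> simulation per regimen ->
    NCA -> population summaries / VPC envelopes -> percent changes

and writes CSV/JSON tables (plus optional SVG plots) and a manifest logging
every parameter, toggle and seed used.  All randomness flows from one root
seed through ``numpy.random.SeedSequence`` sub-spawning, so identical configs
yield byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import yaml

from .clearance import build_clearance_set
from .drug import DrugParameters, load_drug
from .engine import DosingRegimen, PBPKModel, default_time_grid
from .nca import (percent_change, run_nca, summarize_population_auc,
                  vpc_envelope, PopulationSummary)
from .physiology import (DiseaseSpec, PopulationSpec, apply_disease,
                         build_reference_adult, population_to_frame,
                         sample_population)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_stage"]


@dataclass
class RunConfig:
    """One-file configuration of a full pipeline run."""

    drug_file: str | None = None          # None -> shipped HCQ record
    population: PopulationSpec = field(default_factory=lambda: PopulationSpec(n=100))
    regimens: Dict[str, DosingRegimen] = field(default_factory=lambda: {
        "iv_155": DosingRegimen(route="iv_infusion", dose_base=155.0,
                                infusion_duration=30.0),
        "oral_155": DosingRegimen(route="oral", dose_base=155.0),
    })
    stages: List[str] = field(default_factory=lambda: ["healthy"])
    output_dir: str = "hcqpbpk_run"
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9
    grid_t_end: float = 72.0
    grid_dt: float = 0.25
    make_plots: bool = True
    eq_form: str = "as_printed"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "population" in raw:
            pop = dict(raw["population"])
            for key in ("age_range", "weight_range"):
                if key in pop:
                    pop[key] = tuple(pop[key])
            raw["population"] = PopulationSpec(**pop)
        if "regimens" in raw:
            raw["regimens"] = {k: DosingRegimen(**v) for k, v in raw["regimens"].items()}
        return cls(**raw)


def simulate_stage(
    drug: DrugParameters,
    individuals: Sequence,
    regimen: DosingRegimen,
    reference,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
):
    """Simulate every individual of one (stage, regimen) cell.

    Returns (profiles, nca_results).  Solver tolerances are relaxed relative
    to the engine defaults for population throughput; the profiles are smooth
    and NCA metrics converge well before 1e-6/1e-9.
    """
    profiles, ncas = [], []
    for ind in individuals:
        sim = PBPKModel(ind, drug, regimen, reference=reference).simulate(
            times=times, rtol=rtol, atol=atol)
        profiles.append(sim.profile)
        ncas.append(run_nca(sim.profile, regimen.dose_base))
    return profiles, ncas


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full pipeline; returns the report bundle as a dict.

    Outputs written to ``config.output_dir``:
      population.csv, nca_<stage>_<regimen>.csv, summaries.json,
      percent_change.json, vpc_<stage>_<regimen>.csv (+ .svg), manifest.json
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    drug = load_drug(config.drug_file)
    times = default_time_grid(config.grid_t_end, config.grid_dt)

    root = np.random.SeedSequence(config.seed)
    pop_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
    spec = PopulationSpec(**{**asdict_population(config.population), "seed": pop_seed})
    healthy = sample_population(spec)
    reference = build_reference_adult("F", 22.6, 63.5)

    population_to_frame(healthy).to_csv(out_dir / "population.csv", index=False,
                                        float_format="%.6g")

    summaries: Dict[str, Dict[str, PopulationSummary]] = {}
    bundle: Dict = {"summaries": {}, "percent_change": {}}
    try:
        for stage in config.stages:
            stage_pop = ([apply_disease(ind, DiseaseSpec.from_stage(stage))
                          for ind in healthy] if stage != "healthy" else healthy)
            summaries[stage] = {}
            for reg_name, regimen in config.regimens.items():
                logger.info("simulating stage=%s regimen=%s n=%d",
                            stage, reg_name, len(stage_pop))
                profiles, ncas = simulate_stage(
                    drug, stage_pop, regimen, reference, times,
                    rtol=config.rtol, atol=config.atol)
                env = vpc_envelope(profiles) if len(profiles) > 1 else None
                summary = summarize_population_auc(
                    ncas, stage, reg_name, seed=pop_seed, envelope=env)
                summaries[stage][reg_name] = summary
                _write_stage_outputs(out_dir, stage, reg_name, ncas, env, config)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # summaries + percent change vs healthy
    for stage, per_reg in summaries.items():
        bundle["summaries"][stage] = {
            reg: _summary_dict(s) for reg, s in per_reg.items()}
    if "healthy" in summaries:
        for stage, per_reg in summaries.items():
            if stage == "healthy":
                continue
            bundle["percent_change"][stage] = {
                reg: percent_change(summaries["healthy"][reg].median_AUC0_t,
                                    s.median_AUC0_t)
                for reg, s in per_reg.items() if reg in summaries["healthy"]}

    with open(out_dir / "summaries.json", "w") as fh:
        json.dump(bundle["summaries"], fh, indent=2, sort_keys=True)
    with open(out_dir / "percent_change.json", "w") as fh:
        json.dump(bundle["percent_change"], fh, indent=2, sort_keys=True)

    manifest = {
        "seed": config.seed, "population_seed": pop_seed,
        "stages": list(config.stages),
        "regimens": {k: asdict(v) if not isinstance(v, dict) else v
                     for k, v in _regimen_dicts(config.regimens).items()},
        "population": asdict_population(config.population),
        "solver": {"rtol": config.rtol, "atol": config.atol,
                   "grid_t_end": config.grid_t_end, "grid_dt": config.grid_dt},
        "eq_form": config.eq_form,
        "drug_file": config.drug_file or "<shipped hcq.yaml>",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def asdict_population(spec: PopulationSpec) -> dict:
    return {
        "n": spec.n, "female_fraction": spec.female_fraction,
        "age_range": tuple(spec.age_range), "weight_range": tuple(spec.weight_range),
        "variability_cv": dict(spec.variability_cv), "seed": spec.seed,
    }


def _regimen_dicts(regimens: Mapping[str, DosingRegimen]) -> dict:
    out = {}
    for name, r in regimens.items():
        d = asdict(r)
        d.pop("times", None)
        out[name] = d
    return out


def _summary_dict(s: PopulationSummary) -> dict:
    return {
        "n": s.n, "median_AUC0_t": round(s.median_AUC0_t, 6),
        "ci95_low": round(s.ci95_low, 6), "ci95_high": round(s.ci95_high, 6),
        "p5_AUC0_t": round(s.p5_AUC0_t, 6), "p95_AUC0_t": round(s.p95_AUC0_t, 6),
    }


def _write_stage_outputs(out_dir: Path, stage: str, reg_name: str,
                         ncas, env, config: RunConfig) -> None:
    import pandas as pd

    nca_df = pd.DataFrame([{
        "Cmax": r.Cmax, "Tmax": r.Tmax, "AUC0_t": r.AUC0_t,
        "AUC0_inf": r.AUC0_inf, "terminal_rate": r.terminal_rate,
        "CL": r.CL, "flagged": r.flagged,
    } for r in ncas])
    nca_df.to_csv(out_dir / f"nca_{stage}_{reg_name}.csv", index=False,
                  float_format="%.6g")
    if env is None:
        return
    env_df = pd.DataFrame({k: env[k] for k in
                           ("times", "mean", "min", "max", "p5", "p95")})
    env_df.to_csv(out_dir / f"vpc_{stage}_{reg_name}.csv", index=False,
                  float_format="%.6g")
    if config.make_plots:
        _plot_vpc(env, out_dir / f"vpc_{stage}_{reg_name}.svg",
                  title=f"{stage} / {reg_name}")


def _plot_vpc(env, path: Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(env["times"], env["p5"], env["p95"], alpha=0.3,
                    label="5th-95th percentile")
    ax.plot(env["times"], env["mean"], lw=1.5, label="mean")
    ax.plot(env["times"], env["min"], ls="--", lw=0.8, label="min/max")
    ax.plot(env["times"], env["max"], ls="--", lw=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("whole-blood concentration (ng/mL)")
    ax.set_yscale("log")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
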