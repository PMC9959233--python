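"""Replicate-trial battery driver.

A battery runs generate -> allocate -> (inject) -> test for N trials per
requested approach and summarizes type I error / power / RMSE. Every random
draw is traceable to (master seed, stream, trial index), so any single
trial can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import approaches as A
from . import models as M
from .approaches import CandidateSet, _stds_selection, fit_h0_placebo
from .cohort import (EffectScenario, GeneratorConfig,
                     generate_natural_history, inject_treatment_effect,
                     randomize_allocation)
from .engine import FitOptions, as_data
from .evaluation import BatteryResult, summary_table

__all__ = ["RunConfig", "run_battery", "run_scenario_grid", "trial_seed"]

# deterministic stream labels for child seeds
_STREAMS = {"generate": 0, "allocate": 1, "inject": 2, "null": 3}


def trial_seed(master: int, stream: str, trial: int) -> tuple:
    return (int(master), _STREAMS[stream], int(trial))


@dataclass
class RunConfig:
    """Configuration of one battery run (YAML-serializable)."""

    approaches: tuple = ("rclrt", "ima")
    candidates: str = "type1"            # type1 | power | mapd
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scenario: Optional[EffectScenario] = None
    n_trials: int = 100
    n_null: int = 50
    seed: int = 0
    alpha: float = 0.05
    route: str = "fo"                    # likelihood route for battery fits
    ftol: float = 1e-7                   # optimizer f-tolerance for battery fits
    cutoff_rule: str = "quantile"
    out_dir: Optional[str] = None

    def __post_init__(self):
        unknown = [a for a in self.approaches if a not in A.APPROACHES]
        if unknown:
            raise KeyError(f"unknown approach id(s): {unknown}")
        if self.candidates not in ("type1", "power", "mapd"):
            raise KeyError(f"unknown candidate set id {self.candidates!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("command", None)
        gen = d.pop("generator", None)
        scen = d.pop("scenario", None)
        if "approaches" in d:
            d["approaches"] = tuple(d["approaches"])
        cfg = cls(**d)
        if gen is not None:
            cfg.generator = GeneratorConfig.from_dict(gen) \
                if isinstance(gen, dict) else gen
        if scen is not None:
            cfg.scenario = EffectScenario(**scen) \
                if isinstance(scen, dict) else scen
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["approaches"] = list(self.approaches)
        d["generator"] = self.generator.to_dict()
        if self.scenario is not None:
            d["scenario"] = dataclasses.asdict(self.scenario)
        return d

    def candidate_set(self) -> CandidateSet:
        return {"type1": CandidateSet.type1, "power": CandidateSet.power,
                "mapd": CandidateSet.mapd_default}[self.candidates]()


def _make_trial_cohort(cfg: RunConfig, trial: int):
    cohort = generate_natural_history(cfg.generator,
                                      trial_seed(cfg.seed, "generate", trial))
    cohort = randomize_allocation(cohort,
                                  trial_seed(cfg.seed, "allocate", trial))
    if cfg.scenario is not None:
        cohort = inject_treatment_effect(cohort, cfg.scenario,
                                         trial_seed(cfg.seed, "inject", trial))
    return cohort


def _run_single_trial(cfg: RunConfig, trial: int, cands: CandidateSet,
                      options: FitOptions) -> dict:
    """Apply every requested approach to one trial cohort, sharing the
    placebo H0 fit and the drug-model selection fits where possible."""
    data = as_data(_make_trial_cohort(cfg, trial))
    null_seed = trial_seed(cfg.seed, "null", trial)
    shared = {a for a in cfg.approaches
              if a in ("stds", "clrt", "rclrt", "mad", "ima")}
    h0_fit = selection = None
    if shared:
        h0_fit = fit_h0_placebo(data, cands.placebo, options)
        if h0_fit.converged and shared - {"ima"}:
            selection = _stds_selection(data, cands, h0_fit, options)
    results = {}
    for a in cfg.approaches:
        if a == "stds":
            results[a] = A.run_stds(data, cands, cfg.alpha, options,
                                    h0_fit=h0_fit, selection=selection)
        elif a == "rclrt":
            results[a] = A.run_rclrt(data, cands, n=cfg.n_null,
                                     seed=null_seed, alpha=cfg.alpha,
                                     options=options, h0_fit=h0_fit,
                                     cutoff_rule=cfg.cutoff_rule,
                                     selection=selection)
        elif a == "clrt":
            results[a] = A.run_clrt(data, cands, n=cfg.n_null,
                                    seed=null_seed, alpha=cfg.alpha,
                                    options=options, h0_fit=h0_fit,
                                    cutoff_rule=cfg.cutoff_rule,
                                    selection=selection)
        elif a == "mad":
            results[a] = A.run_mad(data, cands, options, h0_fit=h0_fit,
                                   selection=selection)
        elif a == "mapd":
            results[a] = A.run_mapd(data, CandidateSet.mapd_default(),
                                    options)
        elif a == "sss":
            results[a] = A.run_sss(data, cands, cfg.alpha, options)
        elif a == "ima":
            results[a] = A.run_ima(data, cands, cfg.alpha, options,
                                   h0_fit=h0_fit)
    return results


def run_battery(cfg: RunConfig, progress=None):
    """Run the battery; returns (summary DataFrame, per-trial DataFrame,
    dict of BatteryResult). Writes summary.csv / trials.csv when
    ``cfg.out_dir`` is set."""
    cands = cfg.candidate_set()
    options = FitOptions(route=cfg.route, ftol=cfg.ftol)
    scen_id = cfg.scenario.id if cfg.scenario is not None else "no_effect"
    truth = cfg.scenario.typical_effect if cfg.scenario is not None else None
    batteries = {a: BatteryResult(approach=a, scenario=scen_id,
                                  n_trials=cfg.n_trials, truth=truth,
                                  is_averaging=a in ("mad", "mapd"))
                 for a in cfg.approaches}
    trial_rows = []
    for trial in range(cfg.n_trials):
        results = _run_single_trial(cfg, trial, cands, options)
        for a, res in results.items():
            b = batteries[a]
            if b.is_averaging:
                if res.h1_weight_fraction is None:
                    b.excluded += 1
                else:
                    b.decisions.append(res.h1_weight_fraction)
            else:
                if res.decision == "inconclusive":
                    b.excluded += 1
                else:
                    b.decisions.append(res.decision == "reject_h0")
            if res.effect_estimate is not None:
                b.estimates.append(res.effect_estimate)
            trial_rows.append({
                "trial": trial, "approach": a, "scenario": scen_id,
                "decision": res.decision, "dofv": res.dofv,
                "critical_value": res.critical_value,
                "effect_estimate": res.effect_estimate,
                "h1_weight_fraction": res.h1_weight_fraction,
                "selected_model": res.selected_model,
                "excluded_fits": res.excluded_fits,
            })
        if progress is not None:
            progress(trial, results)
    trials = pd.DataFrame(trial_rows)
    summary = summary_table(list(batteries.values()))
    if cfg.out_dir:
        _write_outputs(cfg, summary, trials)
    return summary, trials, batteries


def run_scenario_grid(cfg: RunConfig, scenarios=None):
    """Run the battery once per treatment-effect scenario (default: the
    eight-scenario grid {offset, time-linear} x {2, 8 points} x
    {no IIV, 30% CV}) and stack the summaries — one row per approach per
    scenario."""
    scenarios = list(scenarios) if scenarios is not None \
        else EffectScenario.paper_grid()
    summaries, all_trials = [], []
    batteries = {}
    for i, scen in enumerate(scenarios):
        sub = RunConfig.from_dict({**cfg.to_dict(), "out_dir": None})
        sub.scenario = scen
        sub.seed = cfg.seed + i
        s, t, b = run_battery(sub)
        summaries.append(s)
        all_trials.append(t)
        batteries[scen.id] = b
    summary = pd.concat(summaries, ignore_index=True)
    trials = pd.concat(all_trials, ignore_index=True)
    if cfg.out_dir:
        _write_outputs(cfg, summary, trials)
    return summary, trials, batteries


def _write_outputs(cfg: RunConfig, summary, trials):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "summary.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
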