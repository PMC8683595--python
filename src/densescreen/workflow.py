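"""Experiment orchestration: scenarios x repeats, aggregation, output files.

A run simulates ``repeats`` independent cohorts of ``n_women`` and pushes
each cohort through every requested scenario (common random numbers: the
same cohort is reused across scenarios within a repeat, so life-years
gained are paired differences).  Results are reported per 10,000 women as
mean (SE) over repeats, with the ACER of each scenario against the
reference and the incremental frontier over all scenarios in the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import economics, screening, synthetic_data
from .economics import CEPoint, Frontier, ScenarioResult, icer_frontier
from .natural_history import LifeTable
from .params import DiscountSpec, ParameterSet

_COUNT_KEYS = (
    "bc_deaths",
    "screen_detected",
    "radiation_induced",
    "interval_cancers",
    "false_positives",
    "life_years",
    "cost",
)


@dataclass
class RunConfig:
    """Configuration of one experiment."""

    scenarios: list[str] = field(default_factory=lambda: ["reference", "A"])
    n_women: int = 100_000
    repeats: int = 10
    seed: int = 0
    discounting: str = "base"  # "base" (3/3) | "dutch" (4/1.5)
    reference: str = "reference"
    life_table_csv: Optional[str] = None
    parameter_yaml: Optional[str] = None
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.n_women < 1 or self.repeats < 1:
            raise ValueError("n_women and repeats must be at least 1")
        if not self.scenarios:
            raise ValueError("no scenarios requested")
        if self.discounting not in ("base", "dutch"):
            raise ValueError(f"unknown discounting mode {self.discounting!r}")


@dataclass
class ExperimentResult:
    results: list[ScenarioResult]
    frontier: Frontier
    table: pd.DataFrame
    per_repeat: pd.DataFrame
    config: RunConfig
    param_hash: str


def _load_inputs(cfg: RunConfig, params: Optional[ParameterSet],
                 life_table: Optional[LifeTable]):
    if params is None:
        params = (
            ParameterSet.from_yaml(cfg.parameter_yaml)
            if cfg.parameter_yaml
            else ParameterSet()
        )
    if cfg.discounting == "dutch":
        params = params.copy()
        params.discount = DiscountSpec.dutch()
    if life_table is None:
        life_table = (
            LifeTable.from_csv(cfg.life_table_csv)
            if cfg.life_table_csv
            else synthetic_data.generate_life_table()
        )
    params.validate()
    return params, life_table


def repeat_seeds(master_seed: int, repeats: int) -> list[int]:
    """Independent per-repeat cohort seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(repeats, dtype=np.uint32) % (2**31)]


def run_experiment(
    cfg: RunConfig,
    params: Optional[ParameterSet] = None,
    life_table: Optional[LifeTable] = None,
) -> ExperimentResult:
    """Simulate all scenarios, aggregate per 10,000 women, build the frontier."""
    cfg.validate()
    params, life_table = _load_inputs(cfg, params, life_table)

    names = list(dict.fromkeys(cfg.scenarios))
    if cfg.reference not in names:
        names.insert(0, cfg.reference)
    presets = screening.scenario_presets()
    unknown = [s for s in names if s not in presets]
    if unknown:
        raise KeyError(f"unknown scenario name(s): {unknown}")

    rows = []
    for rep, seed in enumerate(repeat_seeds(cfg.seed, cfg.repeats)):
        cohort = synthetic_data.generate_cohort(cfg.n_women, seed, params, life_table)
        for name in names:
            out = screening.simulate_scenario(cohort, presets[name], params)
            life = economics.resolve_outcomes(cohort, out, params)
            totals = economics.totals_per_10k(out, life, cfg.n_women)
            totals.update(repeat=rep, scenario=name)
            rows.append(totals)
    per_repeat = pd.DataFrame(rows)

    # paired incremental outcomes vs the reference, per repeat
    ref = per_repeat[per_repeat.scenario == cfg.reference].set_index("repeat")
    rep_idx = per_repeat["repeat"]
    per_repeat = per_repeat.assign(
        lyg=per_repeat["life_years"].to_numpy()
        - ref["life_years"].reindex(rep_idx).to_numpy(),
        delta_cost_keur=(
            per_repeat["cost"].to_numpy() - ref["cost"].reindex(rep_idx).to_numpy()
        )
        / 1000.0,
    )

    results = []
    points = []
    for name in names:
        sub = per_repeat[per_repeat.scenario == name]
        mean = sub.mean(numeric_only=True)
        if cfg.repeats > 1:
            se = sub.std(numeric_only=True, ddof=1) / np.sqrt(cfg.repeats)
        else:
            se = mean * np.nan
        res = ScenarioResult(
            name=name,
            bc_deaths=mean.bc_deaths,
            screen_detected=mean.screen_detected,
            radiation_induced=mean.radiation_induced,
            interval_cancers=mean.interval_cancers,
            false_positives=mean.false_positives,
            life_years=mean.life_years,
            cost=mean.cost,
            se={k: se[k] for k in (*_COUNT_KEYS, "lyg")},
        )
        if name != cfg.reference:
            res.lyg = mean.lyg
            res.acer = (
                mean.delta_cost_keur / mean.lyg if mean.lyg != 0 else np.nan
            )
            points.append(CEPoint(name, mean.lyg, mean.delta_cost_keur))
        else:
            res.lyg = 0.0
            points.insert(0, CEPoint(name, 0.0, 0.0))
        results.append(res)

    frontier = (
        icer_frontier(points) if len(points) >= 2 else Frontier([])
    )

    table = pd.DataFrame([r.as_row() for r in results])
    if frontier.points:
        labels = {p.name: p for p in frontier.points}
        table["icer_keur_per_lyg"] = [
            labels[n].icer if n in labels and labels[n].icer is not None else np.nan
            for n in table.scenario
        ]
        table["frontier_label"] = [
            labels[n].label if n in labels else "" for n in table.scenario
        ]
    return ExperimentResult(results, frontier, table, per_repeat, cfg, params.content_hash())


def write_results(result: ExperimentResult, out_dir) -> dict[str, Path]:
    """Write results.csv, frontier.csv and a run log; returns the paths."""
    if not result.results:
        raise ValueError("nothing to write: empty result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "results.csv",
        "frontier": out / "frontier.csv",
        "log": out / "run_log.json",
    }
    result.table.to_csv(paths["results"], index=False, float_format="%.6g")
    result.frontier.to_dataframe().to_csv(
        paths["frontier"], index=False, float_format="%.6g"
    )
    log = {
        "seed": result.config.seed,
        "n_women": result.config.n_women,
        "repeats": result.config.repeats,
        "scenarios": result.config.scenarios,
        "discounting": result.config.discounting,
        "parameter_hash": result.param_hash,
    }
    paths["log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    return paths
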