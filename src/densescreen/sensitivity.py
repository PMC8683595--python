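"""Univariate (tornado) and probabilistic sensitivity analysis.

Both analyses compare one strategy pairwise against the reference (the
optimal strategy versus biennial mammography, in the shipped defaults) and
report the pairwise ICER = incremental discounted cost / incremental
discounted life-years.

The tornado runs one paired simulation per parameter bound, everything
else at base values, with common random numbers so bar widths are driven
by the parameter and not by Monte-Carlo noise.

The PSA draws every uncertain parameter from a truncated Normal
parameterised by its point estimate and 95% interval
(sd = (high - low) / (2 x 1.96), truncation by resampling), reruns the
paired simulation per iteration, and summarises the (delta cost, delta
effect) cloud as a cost-effectiveness acceptability curve: the fraction of
iterations with positive net monetary benefit ``lambda * dE - dC`` per
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import economics, screening, synthetic_data
from .natural_history import LifeTable
from .params import ParameterRange, ParameterSet, parameter_ranges


def _paired_delta(
    params: ParameterSet,
    life_table: LifeTable,
    scenario_name: str,
    reference_name: str,
    n_women: int,
    seeds: list[int],
) -> tuple[float, float]:
    """Mean (delta cost euro, delta life-years) per 10,000 women over seeds."""
    presets = screening.scenario_presets()
    d_cost = d_ly = 0.0
    for seed in seeds:
        cohort = synthetic_data.generate_cohort(n_women, seed, params, life_table)
        tot = {}
        for name in (scenario_name, reference_name):
            out = screening.simulate_scenario(cohort, presets[name], params)
            life = economics.resolve_outcomes(cohort, out, params)
            tot[name] = economics.totals_per_10k(out, life, n_women)
        d_cost += tot[scenario_name]["cost"] - tot[reference_name]["cost"]
        d_ly += tot[scenario_name]["life_years"] - tot[reference_name]["life_years"]
    k = len(seeds)
    return d_cost / k, d_ly / k


def pairwise_icer(d_cost: float, d_ly: float) -> float:
    """k euro per LYG."""
    if d_ly == 0:
        return np.nan
    return (d_cost / 1000.0) / d_ly


def univariate_tornado(
    params: ParameterSet,
    life_table: Optional[LifeTable] = None,
    scenario: str = "A",
    reference: str = "reference",
    n_women: int = 20_000,
    repeats: int = 2,
    seed: int = 0,
    ranges: Optional[list[ParameterRange]] = None,
) -> pd.DataFrame:
    """One-way sensitivity of the pairwise ICER to each parameter's range.

    Returns one row per parameter (label, low, high, icer_low, icer_high,
    width), sorted by decreasing bar width for tornado plotting.
    """
    life_table = life_table or synthetic_data.generate_life_table()
    ranges = ranges if ranges is not None else parameter_ranges(params)
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(repeats) % (2**31)]
    base_dc, base_dly = _paired_delta(params, life_table, scenario, reference,
                                      n_women, seeds)
    rows = []
    for pr in ranges:
        icers = {}
        for bound, value in (("low", pr.low), ("high", pr.high)):
            perturbed = params.with_value(pr.path, value)
            dc, dly = _paired_delta(perturbed, life_table, scenario, reference,
                                    n_women, seeds)
            icers[bound] = pairwise_icer(dc, dly)
        rows.append(
            {
                "parameter": pr.label,
                "path": pr.path,
                "low": pr.low,
                "high": pr.high,
                "icer_low": icers["low"],
                "icer_high": icers["high"],
                "width": abs(icers["high"] - icers["low"]),
            }
        )
    df = pd.DataFrame(rows).sort_values("width", ascending=False, ignore_index=True)
    df.attrs["base_icer"] = pairwise_icer(base_dc, base_dly)
    return df


@dataclass
class PSAConfig:
    """Settings of the probabilistic sensitivity analysis."""

    n_iterations: int = 200
    n_women: int = 20_000
    seed: int = 0
    lambda_grid: list[float] = field(
        default_factory=lambda: [float(x) for x in range(0, 52_500, 2_500)]
    )
    redraw_cohort: bool = True  # False: fixed cohort, parameter uncertainty only

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one PSA iteration")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("willingness-to-pay thresholds must be non-negative")


def sample_parameters(
    params: ParameterSet,
    rng: np.random.Generator,
    ranges: Optional[list[ParameterRange]] = None,
) -> tuple[ParameterSet, dict[str, float]]:
    """One PSA draw: truncated Normal per parameter from its 95% interval."""
    ranges = ranges if ranges is not None else [
        r for r in parameter_ranges(params) if not r.univariate_only
    ]
    drawn: dict[str, float] = {}
    out = params
    for pr in ranges:
        mean = params.get_path(pr.path)
        sd = (pr.high - pr.low) / (2 * 1.959963984540054)
        lo, hi = pr.support
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if lo < v < hi:
                break
        else:
            raise ValueError(f"distribution for {pr.path} inconsistent with support")
        drawn[pr.path] = v
        out = out.with_value(pr.path, v)
    return out, drawn


def run_psa(
    config: PSAConfig,
    params: ParameterSet,
    life_table: Optional[LifeTable] = None,
    scenario: str = "A",
    reference: str = "reference",
    ranges: Optional[list[ParameterRange]] = None,
) -> pd.DataFrame:
    """Monte-Carlo parameter uncertainty propagation.

    Returns one row per iteration with the incremental discounted cost
    (euro per 10,000 women), incremental discounted life-years, the
    pairwise ICER, and every sampled parameter value.  Fully reproducible
    from ``config.seed``.
    """
    config.validate()
    life_table = life_table or synthetic_data.generate_life_table()
    master = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    cohort_seeds = master.generate_state(config.n_iterations, dtype=np.uint32) % (2**31)
    rows = []
    for it in range(config.n_iterations):
        drawn_params, drawn = sample_parameters(params, param_rng, ranges)
        seed = int(cohort_seeds[it]) if config.redraw_cohort else int(cohort_seeds[0])
        dc, dly = _paired_delta(
            drawn_params, life_table, scenario, reference, config.n_women, [seed]
        )
        row = {"iteration": it, "delta_cost": dc, "delta_effect": dly,
               "icer_keur_per_lyg": pairwise_icer(dc, dly)}
        row.update(drawn)
        rows.append(row)
    return pd.DataFrame(rows)


def ceac(psa: pd.DataFrame, lambda_grid) -> pd.DataFrame:
    """Probability of cost-effectiveness per willingness-to-pay threshold.

    For each lambda (euro per LYG), the fraction of PSA iterations with
    net monetary benefit ``lambda * delta_effect - delta_cost > 0``.
    """
    if len(psa) == 0:
        raise ValueError("empty PSA output")
    de = psa["delta_effect"].to_numpy()
    dc = psa["delta_cost"].to_numpy()
    rows = [
        {"lambda": lam, "probability": float(np.mean(lam * de - dc > 0))}
        for lam in lambda_grid
    ]
    return pd.DataFrame(rows)
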