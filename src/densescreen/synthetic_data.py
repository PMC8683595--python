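"""Self-contained inputs: life tables, cohorts, and the published CEA summary.

Nothing here requires network access.  The Gompertz-Makeham life table is
a synthetic stand-in for a national female all-cause (minus breast cancer)
life table, with parameters chosen once to give a female-like survival
curve (life expectancy at birth in the low 80s); a real national table can
be supplied as a two-column CSV instead (see
:meth:`densescreen.natural_history.LifeTable.from_csv`).

:func:`draw_variates` / :func:`generate_cohort` produce the per-woman
random inputs of the microsimulation.  All randomness is pre-drawn here,
so a realised cohort can be pushed through any number of screening
scenarios and parameter sets with common random numbers, which is what
makes paired life-years-gained estimates tight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import density as density_mod
from . import natural_history as nh
from .economics import CEPoint
from .natural_history import LifeTable
from .params import ParameterSet

#: Enough columns for the longest shipped schedule (19 rounds for the
#: combined mammography + AP-MRI strategies) with headroom.
MAX_ROUNDS = 26


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass
class GompertzMakehamParams:
    """Gompertz-Makeham hazard mu(a) = makeham + b * exp(gamma * a)."""

    makeham: float = 1.0e-4
    b: float = 3.0e-6
    gamma: float = 0.120
    max_age: int = 100

    def validate(self) -> None:
        if self.makeham < 0 or self.b < 0:
            raise ValueError("hazard components must be non-negative")
        if self.max_age < 1:
            raise ValueError("max_age must be at least 1")


def generate_life_table(p: Optional[GompertzMakehamParams] = None) -> LifeTable:
    """Annual death probabilities q(a) = 1 - exp(-mu(a)), closed at max age."""
    p = p or GompertzMakehamParams()
    p.validate()
    ages = np.arange(p.max_age + 1)
    hazard = p.makeham + p.b * np.exp(p.gamma * ages)
    q = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(q)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Pre-drawn random inputs plus the realised natural history of n women.

    Raw variates (uniforms ``u_*``, standard normals ``z_*``) are sampled
    once per cohort seed; the realised arrays are deterministic functions
    of the variates and a :class:`ParameterSet`, so the same cohort can be
    re-realised under perturbed parameters (tornado / probabilistic
    sensitivity analysis) without breaking pairing.
    """

    n: int
    seed: int
    # raw variates
    u_rank: np.ndarray
    group_u: np.ndarray  # (n, 3): per-age-group ranks ("independent" coupling)
    u_presence: np.ndarray
    u_onset: np.ndarray
    z_growth: np.ndarray
    z_thresh: np.ndarray
    u_ocd: np.ndarray
    u_attend: np.ndarray  # (n, MAX_ROUNDS)
    u_detect: np.ndarray
    u_fp: np.ndarray
    u_induce: np.ndarray
    u_bc_death: np.ndarray
    u_surv_time: np.ndarray
    z_growth_induced: np.ndarray
    z_thresh_induced: np.ndarray
    # realised natural history (filled by realize_natural_history)
    baseline_category: np.ndarray = None  # codes 0..3 at cohort entry
    has_tumor: np.ndarray = None
    onset_age: np.ndarray = None
    tvdt: np.ndarray = None  # (n,) or (n, 3) under the piecewise rule
    self_detect_diam: np.ndarray = None
    sd_age: np.ndarray = None  # clinical surfacing age, +inf if never
    oc_death_age: np.ndarray = None  # other-cause death, mid-year

    @property
    def max_rounds(self) -> int:
        return self.u_attend.shape[1]


def draw_variates(n: int, seed: int, max_rounds: int = MAX_ROUNDS) -> Cohort:
    """Draw every random input for ``n`` women (no parameters involved)."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    return Cohort(
        n=n,
        seed=seed,
        u_rank=rng.random(n),
        group_u=rng.random((n, 3)),
        u_presence=rng.random(n),
        u_onset=rng.random(n),
        z_growth=rng.standard_normal(n),
        z_thresh=rng.standard_normal(n),
        u_ocd=rng.random(n),
        u_attend=rng.random((n, max_rounds)),
        u_detect=rng.random((n, max_rounds)),
        u_fp=rng.random((n, max_rounds)),
        u_induce=rng.random((n, max_rounds)),
        u_bc_death=rng.random(n),
        u_surv_time=rng.random(n),
        z_growth_induced=rng.standard_normal(n),
        z_thresh_induced=rng.standard_normal(n),
    )


def realize_natural_history(
    cohort: Cohort, params: ParameterSet, life_table: LifeTable
) -> Cohort:
    """Map the cohort's raw variates through the natural-history model.

    Women whose tumour would have surfaced clinically before the cohort
    entry age are re-drawn (tumour profile only): the simulated population
    is women alive and without diagnosed breast cancer at entry, which is
    who a screening program invites.
    """
    p = params
    start = p.density.cohort_start_age
    cat0 = density_mod.category_at_age(cohort.u_rank, start, p.density)

    frac = np.zeros(4)
    for code, letter in enumerate(("a", "b", "c", "d")):
        if letter in p.incidence.lifetime_risk:
            frac[code] = nh.presence_fraction(p.incidence, letter)

    has = cohort.u_presence < frac[cat0]
    onset = np.where(has, nh.onset_age_from_uniform(p.incidence, cohort.u_onset), np.nan)
    tvdt = nh.sample_tvdt(np.nan_to_num(onset, nan=60.0), cohort.z_growth, p.growth)
    thresh = nh.sample_self_detection_diameter(p.self_detect, cohort.z_thresh)
    sd_age = np.where(
        has, nh.self_detection_age(np.nan_to_num(onset, nan=60.0), tvdt, thresh, p.growth), np.inf
    )

    # condition on no clinical cancer before cohort entry
    resample_rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 0xE11]))
    for _ in range(100):
        bad = has & (sd_age < start)
        if not bad.any():
            break
        m = int(bad.sum())
        u_pres = resample_rng.random(m)
        u_on = resample_rng.random(m)
        z_g = resample_rng.standard_normal(m)
        z_t = resample_rng.standard_normal(m)
        has_b = u_pres < frac[cat0[bad]]
        onset_b = np.where(has_b, nh.onset_age_from_uniform(p.incidence, u_on), np.nan)
        tvdt_b = nh.sample_tvdt(np.nan_to_num(onset_b, nan=60.0), z_g, p.growth)
        thresh_b = nh.sample_self_detection_diameter(p.self_detect, z_t)
        sd_b = np.where(
            has_b,
            nh.self_detection_age(np.nan_to_num(onset_b, nan=60.0), tvdt_b, thresh_b, p.growth),
            np.inf,
        )
        has[bad] = has_b
        onset[bad] = onset_b
        tvdt[bad] = tvdt_b
        thresh[bad] = thresh_b
        sd_age[bad] = sd_b

    oc_year = life_table.death_years_from_uniform(int(start), cohort.u_ocd)

    cohort.baseline_category = cat0
    cohort.has_tumor = has
    cohort.onset_age = onset
    cohort.tvdt = tvdt
    cohort.self_detect_diam = thresh
    cohort.sd_age = sd_age
    cohort.oc_death_age = oc_year + 0.5
    return cohort


def generate_cohort(
    n: int,
    seed: int,
    params: Optional[ParameterSet] = None,
    life_table: Optional[LifeTable] = None,
    max_rounds: int = MAX_ROUNDS,
) -> Cohort:
    """Draw and realise a cohort in one step."""
    params = params or ParameterSet()
    life_table = life_table or generate_life_table()
    cohort = draw_variates(n, seed, max_rounds)
    return realize_natural_history(cohort, params, life_table)


# ---------------------------------------------------------------------------
# Published cost-effectiveness summary (reconstruction fixture)
# ---------------------------------------------------------------------------

#: Discounted life-years gained and average cost-effectiveness ratio
#: (k euro per LYG, 3%/3% discounting, per 10,000 women) as published for
#: the Dutch dense-breast AP-MRI screening evaluation this package
#: reimplements.  Strategies: A-F biennial, "-3" triennial, "-4"
#: quadrennial; the reference (biennial mammography 50-74) is the origin.
REPORTED_CEA: dict[str, tuple[float, float]] = {
    "A": (132.0, 16.0),
    "B": (145.0, 17.8),
    "C": (149.0, 18.8),
    "D": (501.0, 21.7),
    "E": (554.0, 23.9),
    "F": (562.0, 25.7),
    "A-3": (91.0, 15.1),
    "B-3": (95.0, 15.5),
    "C-3": (98.0, 17.0),
    "D-3": (334.0, 20.3),
    "E-3": (353.0, 21.4),
    "F-3": (362.0, 23.6),
    "A-4": (52.0, 14.7),
    "B-4": (59.0, 17.3),
    "C-4": (60.0, 18.2),
    "D-4": (158.0, 23.4),
    "E-4": (204.0, 25.9),
    "F-4": (205.0, 27.5),
}


def reported_cea_points(reference_name: str = "reference") -> list[CEPoint]:
    """Incremental (effect, cost) points reconstructed from the published
    summary: effect = reported discounted LYG, cost = reported ACER x LYG
    (k euro per 10,000 women), plus the reference at the origin."""
    pts = [CEPoint(reference_name, 0.0, 0.0)]
    for name, (lyg, acer_keur) in REPORTED_CEA.items():
        pts.append(CEPoint(name, lyg, acer_keur * lyg))
    return pts


def reported_cea_table() -> pd.DataFrame:
    rows = [
        {"scenario": k, "lyg": v[0], "acer_keur_per_lyg": v[1], "cost_keur": v[0] * v[1]}
        for k, v in REPORTED_CEA.items()
    ]
    return pd.DataFrame(rows)
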