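"""Health-economic outcomes: discounting, costs, ACER and the ICER frontier.

Costs and life-years are discounted annually to the cohort entry age
(50 by default).  Point costs (screens, biopsies after a false positive,
treatment at detection) are discounted at the event age; life-years accrue
continuously and each year lived is discounted at its mid-point.

The incremental cost-effectiveness frontier is the lower convex hull of
the (effect, cost) cloud: strictly dominated strategies (another strategy
gains at least as much for no more money, with one inequality strict) are
removed first, then extended-dominated strategies (above the hull, i.e.
their ICER against the preceding frontier member exceeds that of a later
strategy against the same member) are removed iteratively.  ICERs are
reported against the preceding frontier member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import CostParams, DiscountSpec, ParameterSet, SurvivalParams
from .natural_history import bc_death_from_uniforms, size_class


# ---------------------------------------------------------------------------
# Discounting
# ---------------------------------------------------------------------------

def discount_factor(event_age: np.ndarray, rate: float, reference_age: float) -> np.ndarray:
    return (1.0 + rate) ** -(np.asarray(event_age, dtype=float) - reference_age)


def discount(amount: float, event_age: float, rate: float, spec: DiscountSpec) -> float:
    """Present value at the reference age of ``amount`` paid at ``event_age``."""
    if np.any(np.asarray(event_age) < spec.reference_age):
        raise ValueError("event precedes the discounting reference age")
    return amount * discount_factor(event_age, rate, spec.reference_age)


def discounted_life_years(
    death_age: np.ndarray, rate: float, reference_age: float = 50.0
) -> np.ndarray:
    """Discounted life-years lived from the reference age until death.

    Each whole year lived contributes ``v**(k + 0.5)`` (mid-year
    discounting) and the final part-year contributes proportionally at its
    year's mid-point factor.
    """
    years = np.clip(np.asarray(death_age, dtype=float) - reference_age, 0.0, None)
    if rate == 0.0:
        return years
    v = 1.0 / (1.0 + rate)
    k = np.floor(years)
    frac = years - k
    whole = np.sqrt(v) * (1.0 - v**k) / (1.0 - v)
    return whole + frac * v ** (k + 0.5)


# ---------------------------------------------------------------------------
# Per-woman history and cost accumulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenEvent:
    age: float
    modality: str  # "mammography" | "ap_mri"
    attended: bool
    result: str  # "TP" | "FP" | "TN" | "FN" | "NA"


@dataclass
class WomanHistory:
    """One realised life course, for inspection and per-woman accounting."""

    baseline_category: str
    screens: list[ScreenEvent] = field(default_factory=list)
    detection_mode: str = "none"  # "screen" | "interval" | "none"
    detection_age: Optional[float] = None
    detection_diameter: Optional[float] = None
    death_age: float = np.nan
    died_of_breast_cancer: bool = False
    cumulative_dose_mgy: float = 0.0


def accumulate_costs(
    history: WomanHistory,
    costs: CostParams,
    spec: DiscountSpec,
    survival: SurvivalParams,
    mammography_cost: float = 68.0,
    ap_mri_cost: float = 272.0,
    ap_mri_extra: float = 55.0,
) -> float:
    """Discounted lifetime cost of one woman's history.

    Every attended screen costs its modality price (AP-MRI including the
    implementation surcharge), every false positive adds a biopsy, and a
    detected cancer adds one treatment cost for its size class at the
    detection age.
    """
    total = 0.0
    for ev in history.screens:
        if not ev.attended:
            continue
        unit = mammography_cost if ev.modality == "mammography" else ap_mri_cost + ap_mri_extra
        total += discount(unit, ev.age, spec.rate_costs, spec)
        if ev.result == "FP":
            total += discount(costs.biopsy, ev.age, spec.rate_costs, spec)
    if history.detection_mode != "none":
        cls = int(size_class(history.detection_diameter, survival))
        total += discount(
            costs.treatment[cls], history.detection_age, spec.rate_costs, spec
        )
    return total


# ---------------------------------------------------------------------------
# Aggregated scenario results
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Per-10,000-women outcomes of one scenario, mean (SE) over repeats."""

    name: str
    bc_deaths: float
    screen_detected: float
    radiation_induced: float
    interval_cancers: float
    false_positives: float
    life_years: float  # discounted, per 10,000
    cost: float  # discounted euros, per 10,000
    lyg: float = np.nan  # vs reference
    acer: float = np.nan  # k euro / LYG vs reference
    se: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "scenario": self.name,
            "bc_deaths": self.bc_deaths,
            "bc_deaths_se": self.se.get("bc_deaths", np.nan),
            "screen_detected": self.screen_detected,
            "screen_detected_se": self.se.get("screen_detected", np.nan),
            "radiation_induced": self.radiation_induced,
            "radiation_induced_se": self.se.get("radiation_induced", np.nan),
            "interval_cancers": self.interval_cancers,
            "interval_cancers_se": self.se.get("interval_cancers", np.nan),
            "lyg": self.lyg,
            "lyg_se": self.se.get("lyg", np.nan),
            "acer_keur_per_lyg": self.acer,
        }
        row.update(
            {
                "false_positives": self.false_positives,
                "false_positives_se": self.se.get("false_positives", np.nan),
                "life_years_disc": self.life_years,
                "cost_disc_eur": self.cost,
            }
        )
        return row


def acer(
    cost: float, effect: float, reference_cost: float, reference_effect: float
) -> float:
    """Average cost-effectiveness ratio versus a fixed reference."""
    d_e = effect - reference_effect
    if d_e == 0.0:
        raise ZeroDivisionError("ACER undefined: zero incremental effect")
    return (cost - reference_cost) / d_e


# ---------------------------------------------------------------------------
# Life-course resolution and per-10,000 aggregation
# ---------------------------------------------------------------------------

@dataclass
class LifecourseOutcome:
    """Per-woman final outcomes after applying survival to a screening run."""

    death_age: np.ndarray
    died_of_bc: np.ndarray
    induced_expressed: np.ndarray
    disc_life_years: np.ndarray
    disc_cost: np.ndarray


def resolve_outcomes(cohort, screening_out, params: ParameterSet) -> LifecourseOutcome:
    """Apply breast-cancer survival and accounting to a screening run.

    The first-detected tumour drives survival: with the size class's death
    probability the woman dies of breast cancer after an exponential
    survival time; her realised death is the earlier of breast-cancer and
    other-cause death (a tie within the same year is recorded as a
    breast-cancer death).  To avoid crediting lead time, the survival
    clock starts at the tumour's clinical-surfacing age (when it would
    have self-detected), which is scenario-independent; early detection
    improves the outcome through the size class at detection (higher cure
    probability, longer mean survival), not by moving the clock.  A
    radiation-induced tumour counts as expressed if it was the detected
    tumour, or if it crosses its self-detection threshold before the
    realised death.
    """
    p = params
    out = screening_out
    oc_age = cohort.oc_death_age
    detected = out.mode > 0

    # survival anchor: clinical surfacing age of the detected tumour,
    # falling back to the detection age for tumours that never surface
    anchor = np.where(out.det_induced, out.ind_sd_age, cohort.sd_age)
    anchor = np.where(np.isfinite(anchor), anchor, out.det_age)
    diam = np.where(detected, out.det_diam, 1.0)
    dies_bc, bc_age = bc_death_from_uniforms(
        p.survival, diam, np.where(detected, anchor, 0.0),
        cohort.u_bc_death, cohort.u_surv_time,
    )
    dies_bc = dies_bc & detected
    same_year = np.floor(bc_age) == np.floor(oc_age)
    died_of_bc = dies_bc & ((bc_age <= oc_age) | same_year)
    death_age = np.where(dies_bc, np.minimum(bc_age, oc_age), oc_age)

    induced_expressed = out.induced & (
        out.det_induced | (out.ind_sd_age < death_age)
    )

    disc_ly = discounted_life_years(
        death_age, p.discount.rate_effects, p.discount.reference_age
    )
    cls = size_class(out.det_diam, p.survival)
    treat = np.where(
        detected,
        np.asarray(p.costs.treatment)[cls]
        * discount_factor(
            np.where(detected, out.det_age, p.discount.reference_age),
            p.discount.rate_costs,
            p.discount.reference_age,
        ),
        0.0,
    )
    disc_cost = out.disc_screen_cost + out.disc_fp_cost + treat
    return LifecourseOutcome(death_age, died_of_bc, induced_expressed, disc_ly, disc_cost)


def totals_per_10k(
    screening_out, life: LifecourseOutcome, n: int, per: float = 10_000.0
) -> dict[str, float]:
    """Scale a cohort run to the reporting population of 10,000 women."""
    s = per / n
    return {
        "bc_deaths": float(life.died_of_bc.sum()) * s,
        "screen_detected": float((screening_out.mode == 1).sum()) * s,
        "interval_cancers": float((screening_out.mode == 2).sum()) * s,
        "radiation_induced": float(life.induced_expressed.sum()) * s,
        "false_positives": float(screening_out.fp_count.sum()) * s,
        "life_years": float(life.disc_life_years.sum()) * s,
        "cost": float(life.disc_cost.sum()) * s,
    }


# ---------------------------------------------------------------------------
# ICER frontier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEPoint:
    """A strategy's incremental effect and cost versus the common reference."""

    name: str
    effect: float
    cost: float


@dataclass
class LabeledPoint:
    name: str
    effect: float
    cost: float
    label: str  # "frontier" | "dominated" | "extended-dominated"
    icer: Optional[float] = None


@dataclass
class Frontier:
    points: list[LabeledPoint]

    @property
    def frontier_names(self) -> list[str]:
        return [p.name for p in self.points if p.label == "frontier"]

    def icer_of(self, name: str) -> Optional[float]:
        for p in self.points:
            if p.name == name:
                return p.icer
        raise KeyError(name)

    def label_of(self, name: str) -> str:
        for p in self.points:
            if p.name == name:
                return p.label
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scenario": p.name,
                    "effect": p.effect,
                    "cost": p.cost,
                    "label": p.label,
                    "icer": p.icer,
                }
                for p in self.points
            ]
        )


def icer_frontier(points: list[CEPoint]) -> Frontier:
    """Efficient frontier with strict and extended dominance.

    Ties in effect are resolved by keeping the cheaper strategy.  The
    first frontier member's ICER is computed against the least effective
    frontier point (normally the reference at (0, 0)), each subsequent one
    against its frontier predecessor.
    """
    if len(points) < 2:
        raise ValueError("need at least two points (including the reference)")
    order = sorted(range(len(points)), key=lambda i: (points[i].effect, points[i].cost))
    pts = [points[i] for i in order]

    label = {}
    # strict dominance (O(n^2); point counts are small)
    for p in pts:
        for q in pts:
            if q is p:
                continue
            if q.effect >= p.effect and q.cost <= p.cost and (
                q.effect > p.effect or q.cost < p.cost
            ):
                label[p.name] = "dominated"
                break

    candidates = [p for p in pts if p.name not in label]
    # lower convex hull over the remaining points
    stack: list[CEPoint] = []
    for p in candidates:
        while len(stack) >= 2:
            a, b = stack[-2], stack[-1]
            icer_b = (b.cost - a.cost) / (b.effect - a.effect)
            icer_p = (p.cost - a.cost) / (p.effect - a.effect)
            if icer_b >= icer_p:
                label[b.name] = "extended-dominated"
                stack.pop()
            else:
                break
        stack.append(p)

    icers: dict[str, float] = {}
    for prev, cur in zip(stack[:-1], stack[1:]):
        icers[cur.name] = (cur.cost - prev.cost) / (cur.effect - prev.effect)

    labeled = [
        LabeledPoint(
            p.name,
            p.effect,
            p.cost,
            label.get(p.name, "frontier"),
            icers.get(p.name),
        )
        for p in pts
    ]
    return Frontier(labeled)
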