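"""Screening scenarios and the vectorised screening engine.

A :class:`Scenario` assigns each baseline density stratum (BI-RADS c or d
at cohort entry) an ordered set of screening blocks, each a range of ages
screened at a fixed interval with one modality (mammography or
abbreviated-protocol MRI).  Concurrent blocks of *different* modalities
may overlap, which is how the combined mammography+AP-MRI strategies are
expressed.

:func:`simulate_scenario` pushes a realised cohort through a scenario:

* per round, a woman attends with the participation probability (80% by
  default, independently per round);
* an undetected tumour at or above the minimum detectable diameter is
  found with the modality's sensitivity -- constant 0.95 for AP-MRI, and
  for mammography a logistic function of the current diameter d and the
  mean area percent density m of the woman's *current* (age-evolving)
  BI-RADS category, ``(1 - eps) * logistic(b0 + b1 d + b2 m + b3 m/d^2)``
  with a 10% systematic error cap;
* rounds without a true detection yield a false positive with probability
  1 - specificity;
* each attended mammogram adds its dose and can induce a tumour
  (probability dose_Gy x rate per screen) which starts growing after a
  latency and then follows the standard growth model;
* a tumour that crosses its self-detection diameter before the next
  detection opportunity surfaces clinically ("interval" cancer -- the
  label applies to every self-detected cancer, also after the last round);
* detection ends screening for that woman.

All randomness is read from the cohort's pre-drawn variates; the engine
itself is deterministic, which gives common random numbers across
scenarios and parameter sets for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from . import density as density_mod
from . import natural_history as nh
from .economics import ScreenEvent, WomanHistory, discount_factor
from .params import CAT_C, CAT_D, MammographyParams, ParameterSet
from .synthetic_data import Cohort

MOD_NONE, MOD_MAMMO, MOD_MRI = 0, 1, 2
_MOD_CODE = {"mammography": MOD_MAMMO, "ap_mri": MOD_MRI}
_MOD_NAME = {v: k for k, v in _MOD_CODE.items()}

# per-round result codes kept when record collection is on
RES_NONE, RES_TP, RES_FP, RES_TN, RES_FN = 0, 1, 2, 3, 4


# ---------------------------------------------------------------------------
# Test performance
# ---------------------------------------------------------------------------

def mammography_sensitivity(
    d: np.ndarray, m: np.ndarray, p: MammographyParams
) -> np.ndarray:
    """Mammography sensitivity at diameter ``d`` (mm) and area percent
    density ``m``, capped at ``1 - systematic_error``."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    x = p.beta0 + p.beta1 * d + p.beta2 * np.asarray(m) + p.beta3 * np.asarray(m) / d**2
    s = (1.0 - p.systematic_error) * expit(x)
    return s if s.ndim else float(s)


# ---------------------------------------------------------------------------
# Scenario grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    start_age: int
    end_age: int
    interval_years: int
    modality: str  # "mammography" | "ap_mri"

    def round_ages(self) -> list[int]:
        return list(range(self.start_age, self.end_age + 1, self.interval_years))


@dataclass
class Scenario:
    """A named screening strategy: blocks per baseline density stratum."""

    name: str
    blocks: dict[str, list[Block]] = field(default_factory=dict)  # keys "c", "d"
    participation: Optional[float] = None  # None -> policy default

    def validate(self) -> None:
        for stratum, blocks in self.blocks.items():
            if stratum not in ("c", "d"):
                raise ValueError(f"unknown stratum {stratum!r}")
            per_mod: dict[str, list[Block]] = {}
            for b in blocks:
                if b.modality not in _MOD_CODE:
                    raise ValueError(f"unknown modality {b.modality!r}")
                if b.interval_years < 1 or b.end_age < b.start_age:
                    raise ValueError(f"malformed block {b}")
                per_mod.setdefault(b.modality, []).append(b)
            for mod, bs in per_mod.items():
                bs = sorted(bs, key=lambda b: b.start_age)
                for a, b in zip(bs[:-1], bs[1:]):
                    if b.start_age <= a.end_age:
                        raise ValueError(
                            f"overlapping {mod} blocks in stratum {stratum!r}"
                        )


def build_schedule(scenario: Scenario, stratum: str) -> list[tuple[int, str]]:
    """Ordered (age, modality) rounds for one baseline stratum."""
    scenario.validate()
    rounds: list[tuple[int, str]] = []
    for b in scenario.blocks.get(stratum, []):
        rounds.extend((a, b.modality) for a in b.round_ages())
    rounds.sort()
    ages = [a for a, _ in rounds]
    if len(set(ages)) != len(ages):
        raise ValueError("two screens scheduled at the same age")
    return rounds


def _interval_variant(base: Scenario, name: str, interval: int) -> Scenario:
    blocks = {
        s: [replace(b, interval_years=interval) for b in bs]
        for s, bs in base.blocks.items()
    }
    return Scenario(name, blocks)


def scenario_presets() -> dict[str, Scenario]:
    """The shipped strategies.

    ``reference``: biennial mammography 50-74 for both strata.  A-F:
    biennial AP-MRI for the extremely dense stratum only (A: 50-65 then
    mammography 66-74; B: 50-69 then mammography 70-74; C: 50-74) or for
    both dense strata (D, E, F analogously).  ``X-3``/``X-4``: the same
    blocks at triennial/quadrennial intervals.  H/I: biennial mammography
    50-74 plus quadrennial AP-MRI 51-71 for the extremely dense stratum
    (H) or both strata (I).
    """
    mam = [Block(50, 74, 2, "mammography")]
    mri_5065 = [Block(50, 65, 2, "ap_mri"), Block(66, 74, 2, "mammography")]
    mri_5069 = [Block(50, 69, 2, "ap_mri"), Block(70, 74, 2, "mammography")]
    mri_5074 = [Block(50, 74, 2, "ap_mri")]
    combined = mam + [Block(51, 71, 4, "ap_mri")]

    base = {
        "reference": Scenario("reference", {"c": mam, "d": mam}),
        "A": Scenario("A", {"c": mam, "d": mri_5065}),
        "B": Scenario("B", {"c": mam, "d": mri_5069}),
        "C": Scenario("C", {"c": mam, "d": mri_5074}),
        "D": Scenario("D", {"c": mri_5065, "d": mri_5065}),
        "E": Scenario("E", {"c": mri_5069, "d": mri_5069}),
        "F": Scenario("F", {"c": mri_5074, "d": mri_5074}),
    }
    out = dict(base)
    for letter in "ABCDEF":
        for interval in (3, 4):
            name = f"{letter}-{interval}"
            out[name] = _interval_variant(base[letter], name, interval)
    out["H"] = Scenario("H", {"c": mam, "d": combined})
    out["I"] = Scenario("I", {"c": combined, "d": combined})
    for sc in out.values():
        sc.validate()
    return out


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

@dataclass
class ScreeningOutcome:
    """Per-woman results of one scenario run over a cohort."""

    mode: np.ndarray  # 0 none, 1 screen-detected, 2 interval (self-detected)
    det_age: np.ndarray
    det_diam: np.ndarray
    det_induced: np.ndarray  # detected tumour was radiation-induced
    fp_count: np.ndarray
    disc_screen_cost: np.ndarray
    disc_fp_cost: np.ndarray
    dose_mgy: np.ndarray
    induced: np.ndarray  # an induced tumour exists
    ind_onset: np.ndarray
    ind_sd_age: np.ndarray
    n_attended: np.ndarray
    result_codes: Optional[np.ndarray] = None  # (n, rounds) when collected
    round_ages: Optional[np.ndarray] = None
    round_modality: Optional[np.ndarray] = None  # (n, rounds)


def _union_schedule(scenario: Scenario) -> tuple[list[int], dict[int, np.ndarray]]:
    """Union of round ages across strata and, per stratum code, the
    modality code at each union round (0 where the stratum is idle)."""
    scheds = {CAT_C: build_schedule(scenario, "c"), CAT_D: build_schedule(scenario, "d")}
    ages = sorted({a for s in scheds.values() for a, _ in s})
    table: dict[int, np.ndarray] = {}
    for code, sched in scheds.items():
        by_age = {a: _MOD_CODE[m] for a, m in sched}
        table[code] = np.array([by_age.get(a, MOD_NONE) for a in ages], dtype=np.int8)
    return ages, table


def simulate_scenario(
    cohort: Cohort,
    scenario: Scenario,
    params: ParameterSet,
    collect_records: bool = False,
) -> ScreeningOutcome:
    """Run one scenario over a realised cohort (deterministic)."""
    p = params
    n = cohort.n
    growth = p.growth
    ref_age = p.discount.reference_age
    participation = (
        scenario.participation
        if scenario.participation is not None
        else p.policy.participation
    )

    ages, mod_table = _union_schedule(scenario)
    n_rounds = len(ages)
    if n_rounds > cohort.max_rounds:
        raise ValueError(
            f"scenario needs {n_rounds} rounds but the cohort holds "
            f"{cohort.max_rounds}; regenerate with a larger max_rounds"
        )

    mode = np.zeros(n, dtype=np.int8)
    det_age = np.full(n, np.nan)
    det_diam = np.full(n, np.nan)
    det_induced = np.zeros(n, dtype=bool)
    fp_count = np.zeros(n, dtype=np.int32)
    disc_screen = np.zeros(n)
    disc_fp = np.zeros(n)
    dose = np.zeros(n)
    induced = np.zeros(n, dtype=bool)
    ind_onset = np.full(n, np.nan)
    ind_sd_age = np.full(n, np.inf)
    ind_thresh = np.full(n, np.nan)
    if growth.tvdt_rule == "onset":
        ind_tvdt = np.full(n, np.nan)
    else:
        ind_tvdt = np.full((n, 3), np.nan)
    n_attended = np.zeros(n, dtype=np.int32)

    result_codes = round_mods = None
    if collect_records:
        result_codes = np.zeros((n, n_rounds), dtype=np.int8)
        round_mods = np.zeros((n, n_rounds), dtype=np.int8)

    oc_age = cohort.oc_death_age
    sd_age_sp = np.where(cohort.has_tumor, cohort.sd_age, np.inf)
    thresh_sp = np.clip(
        cohort.self_detect_diam, growth.onset_diameter, growth.max_diameter
    )

    mri_sens = p.ap_mri.sensitivity
    dose_per_screen_gy = p.mammography.dose_mgy / 1000.0
    p_induce = dose_per_screen_gy * p.radiation.rate_per_gy

    def settle_self_detection(up_to: float) -> None:
        """Clinically surface tumours whose threshold is crossed by ``up_to``."""
        undet = mode == 0
        first = np.minimum(sd_age_sp, ind_sd_age)
        hit = undet & (first <= up_to) & (first < oc_age)
        if not hit.any():
            return
        from_induced = ind_sd_age[hit] < sd_age_sp[hit]
        mode[hit] = 2
        det_age[hit] = first[hit]
        det_diam[hit] = np.where(
            from_induced,
            np.clip(ind_thresh[hit], growth.onset_diameter, growth.max_diameter),
            thresh_sp[hit],
        )
        det_induced[hit] = from_induced

    for j, t in enumerate(ages):
        settle_self_detection(float(t))

        if p.policy.stratum_assignment == "baseline":
            strata = cohort.baseline_category
        else:  # dynamic: follow the schedule of the current category
            strata = np.maximum(
                density_mod.category_at_age(cohort.u_rank, float(t), p.density), CAT_C
            )
        modality = np.where(
            strata == CAT_D, mod_table[CAT_D][j], mod_table[CAT_C][j]
        ).astype(np.int8)

        if p.policy.attendance_mode == "per_round":
            attends = cohort.u_attend[:, j] < participation
        else:  # lifetime always/never attenders
            attends = cohort.u_attend[:, 0] < participation

        active = (modality != MOD_NONE) & (mode == 0) & (oc_age > t) & attends
        if collect_records:
            round_mods[:, j] = np.where(modality != MOD_NONE, modality, MOD_NONE)
        if not active.any():
            continue
        n_attended[active] += 1

        # current diameters of spontaneous and induced tumours
        d_all = np.zeros(n)
        sp = active & cohort.has_tumor & (cohort.onset_age <= t)
        if sp.any():
            d_all[sp] = nh.diameter_at_age(
                cohort.onset_age[sp], cohort.tvdt[sp], float(t), growth, check=False
            )
        ind_here = active & induced & (ind_onset <= t)
        d_ind = np.zeros(n)
        if ind_here.any():
            d_ind[ind_here] = nh.diameter_at_age(
                ind_onset[ind_here], ind_tvdt[ind_here], float(t), growth, check=False
            )
        from_ind = d_ind > d_all
        d_all = np.maximum(d_all, d_ind)
        detectable = active & (d_all >= p.policy.min_detectable_diameter)

        # sensitivity per modality
        sens = np.zeros(n)
        mam_det = detectable & (modality == MOD_MAMMO)
        if mam_det.any():
            cat_now = density_mod.category_at_age(
                cohort.u_rank[mam_det], float(t), p.density
            )
            m_now = np.asarray(p.density.area_density)[cat_now]
            sens[mam_det] = mammography_sensitivity(
                d_all[mam_det], m_now, p.mammography
            )
        mri_det = detectable & (modality == MOD_MRI)
        sens[mri_det] = mri_sens

        found = detectable & (cohort.u_detect[:, j] < sens)
        mode[found] = 1
        det_age[found] = float(t)
        det_diam[found] = d_all[found]
        det_induced[found] = from_ind[found]

        # false positives in rounds without a true detection
        fp_prob = np.where(
            modality == MOD_MAMMO,
            1.0 - p.mammography.specificity,
            1.0 - p.ap_mri.specificity,
        )
        fp = active & ~found & (cohort.u_fp[:, j] < fp_prob)
        fp_count[fp] += 1
        df_cost = discount_factor(float(t), p.discount.rate_costs, ref_age)
        disc_fp[fp] += p.costs.biopsy * df_cost

        # screening costs
        unit = np.where(
            modality == MOD_MAMMO,
            p.mammography.cost,
            p.ap_mri.cost + p.ap_mri.extra_cost,
        )
        disc_screen[active] += unit[active] * df_cost

        # dose and radiation induction (mammography only)
        mam_active = active & (modality == MOD_MAMMO)
        if mam_active.any() and p.mammography.dose_mgy > 0:
            dose[mam_active] += p.mammography.dose_mgy
            new_ind = mam_active & ~induced & (cohort.u_induce[:, j] < p_induce)
            if new_ind.any():
                induced[new_ind] = True
                onset_i = t + p.radiation.latency_years
                ind_onset[new_ind] = onset_i
                ind_tvdt[new_ind] = nh.sample_tvdt(
                    np.full(int(new_ind.sum()), float(onset_i)),
                    cohort.z_growth_induced[new_ind],
                    growth,
                )
                th = nh.sample_self_detection_diameter(
                    p.self_detect, cohort.z_thresh_induced[new_ind]
                )
                ind_thresh[new_ind] = th
                ind_sd_age[new_ind] = nh.self_detection_age(
                    ind_onset[new_ind], ind_tvdt[new_ind], th, growth
                )

        if collect_records:
            result_codes[active & found, j] = RES_TP
            result_codes[fp, j] = RES_FP
            missed = detectable & ~found & ~fp
            result_codes[missed, j] = RES_FN
            clean = active & ~detectable & ~fp
            result_codes[clean, j] = RES_TN

    settle_self_detection(np.inf)

    return ScreeningOutcome(
        mode=mode,
        det_age=det_age,
        det_diam=det_diam,
        det_induced=det_induced,
        fp_count=fp_count,
        disc_screen_cost=disc_screen,
        disc_fp_cost=disc_fp,
        dose_mgy=dose,
        induced=induced,
        ind_onset=ind_onset,
        ind_sd_age=ind_sd_age,
        n_attended=n_attended,
        result_codes=result_codes,
        round_ages=np.asarray(ages, dtype=float),
        round_modality=round_mods,
    )


def extract_history(
    cohort: Cohort, out: ScreeningOutcome, i: int
) -> WomanHistory:
    """Assemble one woman's :class:`WomanHistory` from a recorded run."""
    if out.result_codes is None:
        raise ValueError("run the scenario with collect_records=True first")
    letters = {RES_TP: "TP", RES_FP: "FP", RES_TN: "TN", RES_FN: "FN"}
    screens = []
    for j, age in enumerate(out.round_ages):
        mod = int(out.round_modality[i, j])
        if mod == MOD_NONE:
            continue
        code = int(out.result_codes[i, j])
        screens.append(
            ScreenEvent(
                age=float(age),
                modality=_MOD_NAME[mod],
                attended=code != RES_NONE,
                result=letters.get(code, "NA"),
            )
        )
    mode_name = {0: "none", 1: "screen", 2: "interval"}[int(out.mode[i])]
    return WomanHistory(
        baseline_category="abcd"[int(cohort.baseline_category[i])],
        screens=screens,
        detection_mode=mode_name,
        detection_age=float(out.det_age[i]) if out.mode[i] else None,
        detection_diameter=float(out.det_diam[i]) if out.mode[i] else None,
        cumulative_dose_mgy=float(out.dose_mgy[i]),
    )
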