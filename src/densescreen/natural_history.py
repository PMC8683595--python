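"""Natural history of invasive breast cancer for one simulated woman.

This module provides the building blocks of a woman's life course absent
screening: whether and when a tumour arises, how fast it grows, when it
would surface clinically, when the woman dies of other causes, and her
breast-cancer survival conditional on tumour size at detection.

All samplers exist in two flavours: a scalar convenience form operating on
a ``numpy.random.Generator`` (useful interactively and in tests) and a
vectorised form driven by pre-drawn uniform/normal variates, which is what
the screening engine uses so that common random numbers are shared across
scenarios.

Model summary
-------------
* At most one spontaneous tumour per woman.  The presence probability per
  baseline density category is normalised so that the probability of onset
  on or before the risk horizon (age 75) equals the configured lifetime
  risk; onset age is Normal(67.9, 21.1) truncated below at 20 years.
* Tumour volume grows exponentially with a log-normally distributed volume
  doubling time (TVDT); by spherical equivalence the diameter is
  ``d(t) = d0 * 2**(dt_days / (3 * TVDT))``, capped at a maximum diameter.
* The clinical (self-)detection diameter is log-normal with median
  ``exp(2.9) ~ 18.2 mm``.
* Other-cause mortality follows an annual life table via sequential
  Bernoulli trials; death is placed mid-way through the death year.
* After detection, breast-cancer death occurs with a size-class-specific
  probability, after an exponential survival time; the realised death is
  the earlier of breast-cancer and other-cause death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .params import GrowthParams, IncidenceParams, SelfDetectParams, SurvivalParams

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# Incidence
# ---------------------------------------------------------------------------

def presence_fraction(incidence: IncidenceParams, category: str) -> float:
    """Probability that a woman of the given baseline category ever
    develops a spontaneous tumour.

    The fraction ``f`` is normalised against the truncated-normal onset
    distribution so that ``P(onset <= risk_horizon_age) = lifetime_risk``
    exactly: ``f = L * (1 - Phi(z_min)) / (Phi(z_h) - Phi(z_min))`` with
    ``z_min``/``z_h`` the standardised truncation bound and horizon.
    """
    if category not in incidence.lifetime_risk:
        raise KeyError(f"unknown density category: {category!r}")
    risk = incidence.lifetime_risk[category]
    if risk == 0.0:
        return 0.0
    z_min = (incidence.min_onset_age - incidence.onset_mean) / incidence.onset_sd
    z_h = (incidence.risk_horizon_age - incidence.onset_mean) / incidence.onset_sd
    f = risk * (1.0 - ndtr(z_min)) / (ndtr(z_h) - ndtr(z_min))
    if f > 1.0:
        raise ValueError(
            f"lifetime risk {risk} is unattainable under the onset model (f={f:.3f})"
        )
    return float(f)


def onset_age_from_uniform(incidence: IncidenceParams, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of the truncated-normal onset age."""
    z_min = (incidence.min_onset_age - incidence.onset_mean) / incidence.onset_sd
    p0 = ndtr(z_min)
    return incidence.onset_mean + incidence.onset_sd * ndtri(p0 + np.asarray(u) * (1.0 - p0))


def sample_tumor(
    incidence: IncidenceParams, category: str, rng: np.random.Generator
) -> Optional[float]:
    """Return the onset age of a spontaneous tumour, or None.

    A tumour is present with :func:`presence_fraction`; given presence the
    onset age is drawn from the truncated normal.
    """
    f = presence_fraction(incidence, category)
    if rng.uniform() >= f:
        return None
    return float(onset_age_from_uniform(incidence, rng.uniform()))


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def lognormal_from_mean_sd(mean: float, sd: float, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws through the log-normal with the given
    natural-scale mean and standard deviation (moment matching)."""
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return np.exp(mu + np.sqrt(s2) * np.asarray(z))


def tvdt_group_of_age(age: np.ndarray, growth: GrowthParams) -> np.ndarray:
    """TVDT age group index: 0 below the first break, 1 between the breaks
    (inclusive upper edge), 2 above."""
    age = np.asarray(age)
    b1, b2 = growth.age_breaks
    return np.where(age < b1, 0, np.where(age <= b2, 1, 2))


def sample_tvdt(onset_age: np.ndarray, z: np.ndarray, growth: GrowthParams) -> np.ndarray:
    """TVDT draw(s) for tumours with the given onset ages.

    Under ``tvdt_rule="onset"`` returns shape (n,): the TVDT of the onset
    age group.  Under ``"piecewise"`` returns shape (n, 3): one TVDT per
    age group, all mapped from the same standard-normal draw so that the
    tumour keeps its relative growth rank when crossing a boundary.
    """
    z = np.asarray(z, dtype=float)
    means = np.asarray(growth.tvdt_mean_days)
    sds = np.asarray(growth.tvdt_sd_days)
    if growth.tvdt_rule == "onset":
        g = tvdt_group_of_age(onset_age, growth)
        s2 = np.log1p((sds / means) ** 2)
        mu = np.log(means) - 0.5 * s2
        return np.exp(mu[g] + np.sqrt(s2[g]) * z)
    cols = [lognormal_from_mean_sd(means[g], sds[g], z) for g in range(3)]
    return np.stack(cols, axis=-1)


def _doubling_rates(tvdt: np.ndarray, growth: GrowthParams) -> np.ndarray:
    """Diameter doublings per year: one volume doubling per TVDT means one
    diameter doubling per 3*TVDT."""
    return DAYS_PER_YEAR / (3.0 * np.asarray(tvdt, dtype=float))


def _band_durations(onset: np.ndarray, age: np.ndarray, growth: GrowthParams) -> np.ndarray:
    """Years spent in each TVDT age band between onset and ``age``, shape (n, 3)."""
    onset = np.asarray(onset, dtype=float)
    age = np.asarray(age, dtype=float)
    b1, b2 = growth.age_breaks
    lo = np.array([-np.inf, b1, b2])
    hi = np.array([b1, b2, np.inf])
    start = np.maximum(onset[..., None], lo)
    stop = np.minimum(age[..., None], hi)
    return np.clip(stop - start, 0.0, None)


def doublings_at_age(
    onset_age: np.ndarray, tvdt: np.ndarray, age: np.ndarray, growth: GrowthParams
) -> np.ndarray:
    """Accumulated diameter doublings between onset and ``age``."""
    if growth.tvdt_rule == "onset":
        years = np.asarray(age, dtype=float) - np.asarray(onset_age, dtype=float)
        return years * _doubling_rates(tvdt, growth)
    rates = _doubling_rates(tvdt, growth)  # (n, 3)
    return np.sum(_band_durations(onset_age, age, growth) * rates, axis=-1)


def diameter_at_age(
    onset_age: np.ndarray,
    tvdt: np.ndarray,
    age: np.ndarray,
    growth: GrowthParams,
    check: bool = True,
) -> np.ndarray:
    """Tumour diameter in mm at ``age``, capped at ``growth.max_diameter``.

    Raises ValueError for ages before onset when ``check`` is true (the
    vectorised engine masks instead).
    """
    if check and np.any(np.asarray(age) < np.asarray(onset_age) - 1e-12):
        raise ValueError("diameter requested before tumour onset")
    n_doubl = doublings_at_age(onset_age, tvdt, age, growth)
    d = growth.onset_diameter * np.exp2(np.clip(n_doubl, 0.0, None))
    return np.minimum(d, growth.max_diameter)


def age_at_diameter(
    onset_age: np.ndarray, tvdt: np.ndarray, target: np.ndarray, growth: GrowthParams
) -> np.ndarray:
    """First age at which the tumour reaches ``target`` mm (inverse growth).

    Targets at or below the onset diameter give the onset age; targets at
    or above the diameter cap are never reached (+inf), since growth stops
    at the cap.
    """
    onset_age = np.asarray(onset_age, dtype=float)
    target = np.asarray(target, dtype=float)
    goal = np.log2(np.maximum(target, growth.onset_diameter) / growth.onset_diameter)
    if growth.tvdt_rule == "onset":
        age = onset_age + goal / _doubling_rates(tvdt, growth)
    else:
        rates = np.atleast_2d(_doubling_rates(tvdt, growth))
        onset2 = np.atleast_1d(onset_age)
        goal2 = np.atleast_1d(goal).astype(float)
        b1, b2 = growth.age_breaks
        lo = np.array([-np.inf, b1, b2])
        hi = np.array([b1, b2, np.inf])
        entry = np.maximum(onset2[:, None], lo)
        span = np.clip(hi - entry, 0.0, None)
        cap = span * rates  # doublings available per band (last is +inf)
        cum = np.cumsum(cap, axis=1)
        before = np.concatenate([np.zeros((cum.shape[0], 1)), cum[:, :-1]], axis=1)
        band = np.argmax(goal2[:, None] <= cum + 1e-12, axis=1)
        idx = np.arange(len(goal2))
        age = entry[idx, band] + (goal2 - before[idx, band]) / rates[idx, band]
        age = np.maximum(age, onset2)
        if np.ndim(onset_age) == 0:
            age = age[0]
    reached = target < growth.max_diameter
    return np.where(reached, age, np.inf)


def self_detection_age(
    onset_age: np.ndarray,
    tvdt: np.ndarray,
    threshold_diam: np.ndarray,
    growth: GrowthParams,
) -> np.ndarray:
    """Age at which the tumour crosses its self-detection diameter."""
    return age_at_diameter(onset_age, tvdt, threshold_diam, growth)


def sample_self_detection_diameter(
    sd: SelfDetectParams, z: np.ndarray
) -> np.ndarray:
    """Log-normal clinical detection threshold in mm from standard normals."""
    return np.exp(sd.log_mean + sd.log_sd * np.asarray(z))


# ---------------------------------------------------------------------------
# Other-cause mortality
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Annual other-cause death probabilities q(a) for integer ages 0..max.

    The final entry must be 1 so that no one outlives the table.
    """

    q: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or len(self.q) < 2:
            raise ValueError("life table needs a 1-D array of at least two ages")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("annual death probabilities must be in [0,1]")
        if self.q[-1] != 1.0:
            raise ValueError("life table must close out: q(max_age) must be 1")

    @property
    def max_age(self) -> int:
        return len(self.q) - 1

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        """Read a two-column CSV (age, annual death probability) with header."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("life table CSV needs two columns (age, q)")
        ages = df.iloc[:, 0].to_numpy()
        if not np.array_equal(ages, np.arange(len(ages))):
            raise ValueError("life table ages must be contiguous integers from 0")
        return cls(df.iloc[:, 1].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": np.arange(len(self.q)), "q": self.q}).to_csv(
            path, index=False
        )

    def death_year_cdf(self, current_age: int) -> np.ndarray:
        """CDF over the death year for someone alive at ``current_age``:
        entry k is P(death year <= current_age + k)."""
        a = int(current_age)
        if a > self.max_age:
            raise ValueError("current age beyond the life table")
        q = self.q[a:]
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q[:-1])])
        return np.cumsum(surv * q)

    def death_years_from_uniform(self, current_age: int, u: np.ndarray) -> np.ndarray:
        """Vectorised death-year sampler (integer age of the death year)."""
        cdf = self.death_year_cdf(current_age)
        k = np.searchsorted(cdf, np.asarray(u), side="right")
        k = np.minimum(k, len(cdf) - 1)
        return int(current_age) + k

    def expected_death_age(self, current_age: int) -> float:
        """Mean realised death age (death placed mid-year), conditional on
        being alive at ``current_age``.  Deterministic oracle for the
        Bernoulli sampler."""
        cdf = self.death_year_cdf(current_age)
        pmf = np.diff(np.concatenate([[0.0], cdf]))
        years = np.arange(len(pmf)) + current_age
        return float(np.sum(pmf * (years + 0.5)))


def sample_other_cause_death_age(
    life_table: LifeTable, rng: np.random.Generator, current_age: int = 0
) -> int:
    """Sequential annual Bernoulli draw of the other-cause death year."""
    a = int(current_age)
    if a > life_table.max_age:
        raise ValueError("current age beyond the life table")
    for age in range(a, life_table.max_age + 1):
        if rng.uniform() < life_table.q[age]:
            return age
    return life_table.max_age  # unreachable: q(max) == 1


# ---------------------------------------------------------------------------
# Breast-cancer survival
# ---------------------------------------------------------------------------

def size_class(diameter_mm: np.ndarray, survival: SurvivalParams) -> np.ndarray:
    """Tumour size class at detection: 0 (<20 mm), 1 (20-50 mm), 2 (>50 mm)."""
    d = np.asarray(diameter_mm)
    b1, b2 = survival.size_breaks_mm
    return np.where(d < b1, 0, np.where(d <= b2, 1, 2))


def breast_cancer_outcome(
    survival: SurvivalParams,
    size_at_detection: float,
    detection_age: float,
    rng: np.random.Generator,
) -> Optional[float]:
    """Breast-cancer death age for a tumour of the given size at detection,
    or None if the woman is cured with respect to breast cancer."""
    cls = int(size_class(size_at_detection, survival))
    if rng.uniform() >= survival.death_prob[cls]:
        return None
    t = rng.exponential(survival.mean_years[cls])
    return float(detection_age + t)


def bc_death_from_uniforms(
    survival: SurvivalParams,
    diameter: np.ndarray,
    detection_age: np.ndarray,
    u_death: np.ndarray,
    u_time: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised survival outcome: (dies_of_bc, bc_death_age).

    The same uniforms across scenarios keep outcomes paired: a woman cured
    at threshold u in one scenario is cured in any scenario with a lower
    death probability for her detected size class.
    """
    cls = size_class(diameter, survival)
    p = np.asarray(survival.death_prob)[cls]
    mean = np.asarray(survival.mean_years)[cls]
    dies = np.asarray(u_death) < p
    t = -mean * np.log1p(-np.asarray(u_time))
    return dies, np.asarray(detection_age) + t
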