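"""Model parameters for the dense-breast screening microsimulation.

All quantities are grouped into small dataclasses mirroring the model
components (tumour incidence, growth, self-detection, survival, breast
density, test performance, radiation risk, costs, discounting, screening
policy) and aggregated into a single :class:`ParameterSet` that can be
round-tripped through YAML for configuration files.

Default point estimates correspond to a population-based screening setting
for women with mammographically dense (BI-RADS c/d) breasts:

* lifetime breast-cancer risk to age 75 of 15.5% (heterogeneously dense)
  and 20.2% (extremely dense), with tumour onset age ~ Normal(67.9, 21.1);
* log-normal tumour volume doubling times of 80/157/188 days (mean) for
  onset ages <50 / 50-70 / >70;
* log-normal self-detection diameter with log-mean 2.9 ln(mm) and
  log-sd 0.6 (median ~18 mm);
* mammography specificity 0.89 and a size- and density-dependent logistic
  sensitivity capped at 0.90 by a 10% systematic error; abbreviated-protocol
  MRI sensitivity 0.95 and specificity 0.87;
* 2019 unit costs in euros (mammogram 68, AP-MRI 272 + 55 implementation
  surcharge, biopsy 191, treatment 6875/7612/8224 by size class);
* 3%/3% annual discounting of costs and life-years from age 50.

Quantities that are not published for this setting (the logistic
sensitivity coefficients of mammography and the survival-by-size table)
carry documented placeholder defaults calibrated against the reference
screening arm; see ``docs/methods.md``.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

CATEGORY_LETTERS = ("a", "b", "c", "d")

# Codes used throughout the vectorised engine.
CAT_A, CAT_B, CAT_C, CAT_D = 0, 1, 2, 3


@dataclass
class IncidenceParams:
    """Normal-onset-age tumour incidence model.

    A woman develops at most one spontaneous tumour during her life.  The
    probability of ever developing one is chosen per baseline density
    category so that the cumulative probability of onset by
    ``risk_horizon_age`` equals the configured lifetime risk; given
    presence, onset age follows a Normal(onset_mean, onset_sd) truncated
    below at ``min_onset_age``.
    """

    lifetime_risk: dict[str, float] = field(
        default_factory=lambda: {"c": 0.155, "d": 0.202}
    )
    onset_mean: float = 67.9
    onset_sd: float = 21.1
    risk_horizon_age: float = 75.0
    min_onset_age: float = 20.0

    def validate(self) -> None:
        for k, v in self.lifetime_risk.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"lifetime risk for {k!r} must be in [0,1): {v}")
        if self.onset_sd <= 0:
            raise ValueError("onset_sd must be positive")
        if self.risk_horizon_age <= self.min_onset_age:
            raise ValueError("risk horizon must exceed the minimum onset age")


@dataclass
class GrowthParams:
    """Exponential-volume tumour growth.

    Tumour volume doubles every TVDT, so the diameter (spherical
    equivalence) doubles every three TVDTs.  The TVDT is drawn once per
    tumour from the log-normal distribution of an age group; with
    ``tvdt_rule="onset"`` the group of the onset age applies for the whole
    tumour lifetime, with ``"piecewise"`` the doubling rate switches as the
    woman crosses the age-group boundaries (the same standard-normal draw
    is mapped through each group's distribution, so growth is continuous).
    """

    tvdt_mean_days: list[float] = field(default_factory=lambda: [80.0, 157.0, 188.0])
    tvdt_sd_days: list[float] = field(default_factory=lambda: [28.0, 25.0, 52.0])
    age_breaks: list[float] = field(default_factory=lambda: [50.0, 70.0])
    onset_diameter: float = 0.1  # mm
    max_diameter: float = 128.0  # mm
    tvdt_rule: str = "onset"  # "onset" | "piecewise"

    def validate(self) -> None:
        if any(m <= 0 for m in self.tvdt_mean_days) or any(
            s <= 0 for s in self.tvdt_sd_days
        ):
            raise ValueError("TVDT means and sds must be positive")
        if self.onset_diameter <= 0:
            raise ValueError("onset diameter must be positive")
        if self.max_diameter <= self.onset_diameter:
            raise ValueError("max diameter must exceed the onset diameter")
        if self.tvdt_rule not in ("onset", "piecewise"):
            raise ValueError(f"unknown tvdt_rule: {self.tvdt_rule!r}")


@dataclass
class SelfDetectParams:
    """Log-normal diameter at which a tumour surfaces clinically."""

    log_mean: float = 2.9  # ln(mm)
    log_sd: float = 0.6

    def validate(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")


@dataclass
class SurvivalParams:
    """Breast-cancer survival conditional on tumour size at detection.

    Size classes at detection are <20 mm, 20-50 mm and >50 mm.  With the
    class's ``death_prob`` the woman eventually dies of breast cancer,
    after an exponentially distributed time with the class's mean; with the
    complementary probability she is cured with respect to breast cancer.
    The default values are calibrated placeholders (the underlying
    registry-based table is not published for this setting).
    """

    death_prob: list[float] = field(default_factory=lambda: [0.63, 0.97, 1.0])
    mean_years: list[float] = field(default_factory=lambda: [11.0, 2.0, 1.0])
    size_breaks_mm: list[float] = field(default_factory=lambda: [20.0, 50.0])

    def validate(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.death_prob):
            raise ValueError("death probabilities must be in [0,1]")
        if any(b < a for a, b in zip(self.death_prob[:-1], self.death_prob[1:])):
            raise ValueError("death probability must not decrease with size class")
        if any(m <= 0 for m in self.mean_years):
            raise ValueError("mean survival times must be positive")


@dataclass
class DensityParams:
    """Age-dependent BI-RADS density distribution and mean area percent density.

    ``probs`` holds the (a, b, c, d) category probabilities per age group
    [50,60), [60,70), [70,inf).  ``area_density`` is the mean area percent
    density m (scaled to [0,1]) per category, used by the mammography
    sensitivity function.  ``coupling="quantile"`` ties every woman to a
    fixed lifetime density rank so her category can only decrease with age
    while the cross-sectional marginals stay exact; ``"independent"``
    redraws the category independently per age group.
    """

    probs: list[list[float]] = field(
        default_factory=lambda: [
            [0.0, 0.0, 0.67, 0.33],
            [0.0, 0.43, 0.43, 0.14],
            [0.29, 0.35, 0.31, 0.05],
        ]
    )
    age_breaks: list[float] = field(default_factory=lambda: [60.0, 70.0])
    area_density: list[float] = field(default_factory=lambda: [0.06, 0.16, 0.40, 0.83])
    cohort_start_age: float = 50.0
    coupling: str = "quantile"  # "quantile" | "independent"

    def validate(self) -> None:
        for row in self.probs:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"density category probabilities must sum to 1: {row}")
            if any(p < 0 for p in row):
                raise ValueError("density category probabilities must be non-negative")
        m = self.area_density
        if any(b <= a for a, b in zip(m[:-1], m[1:])):
            raise ValueError("area percent density must increase a -> d")
        if self.coupling not in ("quantile", "independent"):
            raise ValueError(f"unknown coupling mode: {self.coupling!r}")


@dataclass
class MammographyParams:
    """Mammography test performance.

    Sensitivity is ``(1 - systematic_error) * logistic(beta0 + beta1*d +
    beta2*m + beta3*m/d**2)`` with d the tumour diameter in mm and m the
    mean area percent density of the woman's current BI-RADS category.  The
    10% systematic error models tumours that are undetectable on
    mammography regardless of size (lobular carcinomas, lesions close to
    the thorax wall), capping sensitivity at 0.90.  The beta coefficients
    are configurable placeholders calibrated against the reference arm.
    """

    beta0: float = -1.1
    beta1: float = 0.38  # per mm diameter
    beta2: float = -1.8  # per unit area percent density
    beta3: float = -8.0  # per unit m/d^2
    systematic_error: float = 0.10
    specificity: float = 0.89
    dose_mgy: float = 3.0  # mean glandular dose per screen
    cost: float = 68.0  # euro per screen, 2019

    def validate(self) -> None:
        if not 0.0 <= self.systematic_error < 1.0:
            raise ValueError("systematic error must be in [0,1)")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError("specificity must be in [0,1]")
        if self.dose_mgy < 0:
            raise ValueError("dose must be non-negative")


@dataclass
class MRIParams:
    """Abbreviated-protocol MRI test performance (density-independent)."""

    sensitivity: float = 0.95
    specificity: float = 0.87
    dose_mgy: float = 0.0
    cost: float = 272.0  # euro per screen, 2019
    extra_cost: float = 55.0  # implementation surcharge per screen

    def validate(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class RadiationParams:
    """Radiation-induced tumour risk from mammography dose.

    Each attended mammogram delivers ``MammographyParams.dose_mgy`` and
    independently induces a tumour with probability ``dose_gy * rate``
    where the rate is ``risk_per_gy`` under ``scale="per_gy"`` or
    ``risk_per_gy / 100`` under ``scale="percent_per_gy"``.  An induced
    tumour starts growing ``latency_years`` after the exposure and then
    follows the standard growth/detection model; it is only counted if it
    surfaces (by screen- or self-detection) before death.
    """

    risk_per_gy: float = 0.51
    scale: str = "per_gy"  # "per_gy" | "percent_per_gy"
    latency_years: float = 25.0

    def validate(self) -> None:
        if self.scale not in ("per_gy", "percent_per_gy"):
            raise ValueError(f"unknown radiation risk scale: {self.scale!r}")
        if self.risk_per_gy < 0:
            raise ValueError("risk per Gy must be non-negative")
        if self.latency_years < 0:
            raise ValueError("latency must be non-negative")

    @property
    def rate_per_gy(self) -> float:
        return self.risk_per_gy / 100.0 if self.scale == "percent_per_gy" else self.risk_per_gy


@dataclass
class CostParams:
    """Unit costs in 2019 euros."""

    biopsy: float = 191.0  # per false positive
    treatment: list[float] = field(default_factory=lambda: [6875.0, 7612.0, 8224.0])

    def validate(self) -> None:
        if self.biopsy < 0 or any(t < 0 for t in self.treatment):
            raise ValueError("costs must be non-negative")
        if any(b < a for a, b in zip(self.treatment[:-1], self.treatment[1:])):
            raise ValueError("treatment cost must not decrease with size class")


@dataclass
class DiscountSpec:
    """Annual discounting of costs and health effects from a reference age."""

    rate_costs: float = 0.03
    rate_effects: float = 0.03
    reference_age: float = 50.0

    def validate(self) -> None:
        if self.rate_costs < 0 or self.rate_effects < 0:
            raise ValueError("discount rates must be non-negative")

    @classmethod
    def base(cls) -> "DiscountSpec":
        return cls(0.03, 0.03)

    @classmethod
    def dutch(cls) -> "DiscountSpec":
        """Dutch guideline discounting: 4% costs, 1.5% effects."""
        return cls(0.04, 0.015)


@dataclass
class ScreeningPolicy:
    """Program-level screening behaviour."""

    participation: float = 0.80
    min_detectable_diameter: float = 2.0  # mm, either modality
    max_age: float = 100.0
    attendance_mode: str = "per_round"  # "per_round" | "per_woman"
    stratum_assignment: str = "baseline"  # "baseline" | "dynamic"

    def validate(self) -> None:
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must be in [0,1]")
        if self.attendance_mode not in ("per_round", "per_woman"):
            raise ValueError(f"unknown attendance mode: {self.attendance_mode!r}")
        if self.stratum_assignment not in ("baseline", "dynamic"):
            raise ValueError(f"unknown stratum assignment: {self.stratum_assignment!r}")


@dataclass
class ParameterSet:
    """Complete parameterisation of the microsimulation."""

    incidence: IncidenceParams = field(default_factory=IncidenceParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    self_detect: SelfDetectParams = field(default_factory=SelfDetectParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    density: DensityParams = field(default_factory=DensityParams)
    mammography: MammographyParams = field(default_factory=MammographyParams)
    ap_mri: MRIParams = field(default_factory=MRIParams)
    radiation: RadiationParams = field(default_factory=RadiationParams)
    costs: CostParams = field(default_factory=CostParams)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    policy: ScreeningPolicy = field(default_factory=ScreeningPolicy)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            getattr(self, f.name).validate()

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        kwargs = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            kwargs[f.name] = f.default_factory().__class__(**sub)  # type: ignore[misc]
        ps = cls(**kwargs)
        ps.validate()
        return ps

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def content_hash(self) -> str:
        """Stable hash of the full parameter content, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- dotted-path access (used by sensitivity analyses) ------------

    def get_path(self, path: str) -> float:
        obj: Any = self
        for part in path.split("."):
            if isinstance(obj, dict):
                obj = obj[part]
            elif isinstance(obj, list):
                obj = obj[int(part)]
            else:
                obj = getattr(obj, part)
        return obj

    def with_value(self, path: str, value: float) -> "ParameterSet":
        """Return a deep copy with the parameter at ``path`` replaced."""
        ps = self.copy()
        parts = path.split(".")
        obj: Any = ps
        for part in parts[:-1]:
            if isinstance(obj, dict):
                obj = obj[part]
            elif isinstance(obj, list):
                obj = obj[int(part)]
            else:
                obj = getattr(obj, part)
        last = parts[-1]
        if isinstance(obj, dict):
            obj[last] = value
        elif isinstance(obj, list):
            obj[int(last)] = value
        else:
            setattr(obj, last, value)
        ps.validate()
        return ps


@dataclass(frozen=True)
class ParameterRange:
    """A parameter with its 95% interval, for tornado and PSA sampling."""

    label: str
    path: str
    low: float
    high: float
    support: tuple[float, float] = (-float("inf"), float("inf"))
    univariate_only: bool = False


def parameter_ranges(params: ParameterSet) -> list[ParameterRange]:
    """The uncertain parameters with published 95% CIs (plus the +/-50%
    AP-MRI unit-cost range used only in the one-way analysis)."""
    mri_cost = params.get_path("ap_mri.cost")
    return [
        ParameterRange("Lifetime risk (BI-RADS c)", "incidence.lifetime_risk.c",
                       0.145, 0.166, (0.0, 1.0)),
        ParameterRange("Lifetime risk (BI-RADS d)", "incidence.lifetime_risk.d",
                       0.188, 0.216, (0.0, 1.0)),
        ParameterRange("Mean onset age", "incidence.onset_mean", 65.7, 70.1,
                       (20.0, 100.0)),
        ParameterRange("Onset age spread", "incidence.onset_sd", 19.2, 22.9,
                       (1e-6, float("inf"))),
        ParameterRange("Self-detection log-mean", "self_detect.log_mean", 2.8, 2.9),
        ParameterRange("Self-detection log-sd", "self_detect.log_sd", 0.4, 0.7,
                       (1e-6, float("inf"))),
        ParameterRange("Tumour induction per Gy", "radiation.risk_per_gy",
                       0.28, 0.83, (0.0, float("inf"))),
        ParameterRange("Mammography dose (mGy)", "mammography.dose_mgy", 1.0, 5.0,
                       (0.0, float("inf"))),
        ParameterRange("Mammography specificity", "mammography.specificity",
                       0.88, 0.89, (0.0, 1.0)),
        ParameterRange("AP-MRI sensitivity", "ap_mri.sensitivity", 0.83, 0.99,
                       (0.0, 1.0)),
        ParameterRange("AP-MRI specificity", "ap_mri.specificity", 0.86, 0.89,
                       (0.0, 1.0)),
        ParameterRange("AP-MRI cost per screen", "ap_mri.cost",
                       0.5 * mri_cost, 1.5 * mri_cost, (0.0, float("inf")),
                       univariate_only=True),
    ]
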