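"""Age-dependent BI-RADS breast density.

Density declines with age.  Only the cross-sectional category distribution
per age group is available, so individual trajectories are constructed by
quantile coupling: every woman carries a fixed lifetime density rank
``u_rank`` in (0,1), and at any age her category is read off the age
group's cumulative distribution ordered from densest (d) to fattiest (a).
Because the d-first cumulative thresholds shrink with age, a woman's
category can only move down the density ordering as she ages, while each
cross-section reproduces the configured marginals exactly.
"""

from __future__ import annotations

import numpy as np

from .params import CATEGORY_LETTERS, DensityParams

# Category codes 0..3 = a..d; density ordering is d > c > b > a.
_DENSEST_FIRST = np.array([3, 2, 1, 0])


def age_group_index(age: float, params: DensityParams) -> int:
    """Index of the density age group containing ``age`` (half-open bins
    [50,60), [60,70), [70,inf) by default)."""
    if age < params.cohort_start_age:
        raise ValueError(
            f"density model starts at age {params.cohort_start_age}; got {age}"
        )
    return int(np.searchsorted(np.asarray(params.age_breaks), age, side="right"))


def category_at_age(
    u_rank: np.ndarray, age: float, params: DensityParams
) -> np.ndarray:
    """BI-RADS category code (0..3 = a..d) at ``age`` for lifetime density
    rank(s) ``u_rank``.

    Small ranks mean dense: a woman with ``u_rank`` below the age group's
    probability of category d is in d, below P(d)+P(c) in c, and so on.
    """
    g = age_group_index(age, params)
    probs = np.asarray(params.probs[g])[_DENSEST_FIRST]
    cum = np.cumsum(probs)
    k = np.searchsorted(cum, np.asarray(u_rank), side="right")
    k = np.minimum(k, 3)
    return _DENSEST_FIRST[k]


def category_letter(code: np.ndarray) -> np.ndarray:
    return np.asarray(CATEGORY_LETTERS)[np.asarray(code)]


def area_percent_density(category, params: DensityParams) -> np.ndarray:
    """Mean area percent density m in [0,1] for a category code or letter."""
    cat = np.asarray(category)
    if cat.dtype.kind in "US":
        lookup = {c: i for i, c in enumerate(CATEGORY_LETTERS)}
        try:
            cat = np.vectorize(lookup.__getitem__)(cat)
        except KeyError as e:
            raise KeyError(f"unknown density category: {e.args[0]!r}") from None
    cat = np.asarray(cat, dtype=int)
    if np.any((cat < 0) | (cat > 3)):
        raise KeyError("density category code must be 0..3")
    out = np.asarray(params.area_density)[cat]
    return out if out.ndim else float(out)
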