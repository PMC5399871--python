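"""Simpson and Shannon diversity of utilization/availability profiles.

Two Simpson variants are exposed because the two common forms are easily
conflated in the ecological literature: the index of diversity
``1 - sum(p_i^2)`` (bounded by [0, 1), the default here) and the inverse
form ``1 / sum(p_i^2)`` (bounded by [1, k]). Shannon diversity is the
standard ``-sum(p_i * log p_i)`` with a selectable log base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ValidationError
from .prey_metrics import UtilizationProfile

SIMPSON_VARIANTS = ("simpson_1mD", "simpson_inverse")


@dataclass(frozen=True)
class DiversityResult:
    index: str
    value: float
    group: str
    k: int
    base: float | None = None

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "index": self.index,
            "value": self.value,
            "k": self.k,
            "base": self.base,
        }


def _props(profile: UtilizationProfile) -> np.ndarray:
    p = profile.proportions
    if p.size == 0:
        raise ValidationError("empty profile")
    return p


def simpson_diversity(
    profile: UtilizationProfile, variant: str = "simpson_1mD"
) -> DiversityResult:
    """Simpson diversity: ``1 - sum(p^2)`` or the inverse form ``1/sum(p^2)``."""
    p = _props(profile)
    concentration = float(np.sum(p**2))
    if variant == "simpson_1mD":
        value = 1.0 - concentration
    elif variant == "simpson_inverse":
        value = 1.0 / concentration
    else:
        raise ValidationError(f"unknown Simpson variant {variant!r}")
    return DiversityResult(variant, value, profile.group, int(np.count_nonzero(p)))


def shannon_diversity(
    profile: UtilizationProfile, base: float = math.e
) -> DiversityResult:
    """Shannon diversity ``H' = -sum(p_i log p_i)``; zero proportions contribute 0."""
    if base not in (math.e, 2, 10):
        raise ValidationError(f"base must be e, 2 or 10, got {base}")
    p = _props(profile)
    nz = p[p > 0]
    value = float(-np.sum(nz * np.log(nz)) / math.log(base))
    return DiversityResult(
        "shannon", value, profile.group, int(nz.size), base=base
    )


def diversity_report(
    profiles: list[UtilizationProfile],
    simpson_variant: str = "simpson_1mD",
    shannon_base: float = math.e,
) -> pd.DataFrame:
    """Simpson + Shannon for each profile, as a tidy report table."""
    rows = []
    for prof in profiles:
        rows.append(simpson_diversity(prof, simpson_variant).as_dict())
        rows.append(shannon_diversity(prof, shannon_base).as_dict())
    return pd.DataFrame(rows)
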