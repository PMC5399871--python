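"""Prey volume estimation and utilization/availability profiles.

Item volumes are approximated by an ellipsoid from linear measures taken with
digital callipers; when only length and width are available the height is
taken equal to the width (prolate spheroid). Profiles are the normalized
proportion vectors that every downstream statistic (diversity, electivity,
overlap) consumes: r_i for diets, p_i for environmental availability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    HABITAT_CLASSES,
    UNIDENTIFIED_TAXON,
    AbundanceTable,
    PreyRecord,
    ValidationError,
)


def ellipsoid_volume(
    length_mm: float, width_mm: float, height_mm: float | None = None
) -> float:
    """Ellipsoid volume (mm^3) from linear measures: (4/3)*pi*(L/2)(W/2)(H/2).

    With no height measure the item is treated as a prolate spheroid
    (height = width). Reduces to the sphere volume when all axes are equal.
    """
    if height_mm is None:
        height_mm = width_mm
    for name, v in (("length", length_mm), ("width", width_mm), ("height", height_mm)):
        if not v > 0:
            raise ValidationError(f"{name} must be positive, got {v}")
    return (4.0 / 3.0) * math.pi * (length_mm / 2) * (width_mm / 2) * (height_mm / 2)


@dataclass(frozen=True)
class UtilizationProfile:
    """Normalized proportions of each taxon in one group's diet or environment.

    ``proportions[i]`` is r_i (diet) or p_i (availability) for ``taxa[i]``;
    zero-count taxa are retained with proportion 0 so profiles from the same
    table are always comparable position by position.
    """

    taxa: tuple[str, ...]
    proportions: np.ndarray
    basis: str = "count"
    group: str = ""
    denominator: float = 0.0

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", props)
        if props.shape != (len(self.taxa),):
            raise ValidationError("proportions and taxa have different lengths")
        if (props < -1e-12).any():
            raise ValidationError("proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError(f"proportions sum to {props.sum()}, not 1")

    def __getitem__(self, taxon: str) -> float:
        return float(self.proportions[self.taxa.index(taxon)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.taxa), name=self.group)

    def restrict(self, taxa: Sequence[str]) -> "UtilizationProfile":
        """Renormalize over a subset of taxa (e.g. the union of two diets)."""
        idx = [self.taxa.index(t) for t in taxa]
        vals = self.proportions[idx]
        total = vals.sum()
        if total <= 0:
            raise ValidationError("empty profile after restriction")
        return UtilizationProfile(
            tuple(taxa), vals / total, self.basis, self.group, self.denominator * total
        )


def profile_from_counts(
    taxa: Sequence[str],
    values: Sequence[float],
    basis: str = "count",
    group: str = "",
    include_unidentified: bool = False,
) -> UtilizationProfile:
    """Normalize a raw value vector into a :class:`UtilizationProfile`.

    By default the ``Unidentified`` taxon is dropped before normalizing, so
    proportions are over identified prey only (the convention used for every
    reported statistic); ``include_unidentified=True`` keeps it.
    """
    taxa = list(taxa)
    values = np.asarray(values, dtype=float)
    if not include_unidentified and UNIDENTIFIED_TAXON in taxa:
        keep = [i for i, t in enumerate(taxa) if t != UNIDENTIFIED_TAXON]
        taxa = [taxa[i] for i in keep]
        values = values[keep]
    if (values < 0).any():
        raise ValidationError("negative values in profile input")
    total = values.sum()
    if total <= 0:
        raise ValidationError(f"empty profile for group {group!r}")
    return UtilizationProfile(tuple(taxa), values / total, basis, group, float(total))


def make_profile(
    table: AbundanceTable,
    group: str,
    basis: str = "count",
    include_unidentified: bool = False,
) -> UtilizationProfile:
    """Proportion profile of one table group, on count or volume basis."""
    if group not in table.groups:
        raise ValidationError(f"group {group!r} not in table (has {table.groups})")
    if basis == "count":
        values = table.counts(group)
    elif basis == "volume":
        values = table.volumes(group)
    else:
        raise ValidationError(f"basis must be 'count' or 'volume', got {basis!r}")
    return profile_from_counts(
        table.taxa, values.to_numpy(), basis, group, include_unidentified
    )


def habitat_class_summary(records: Iterable[PreyRecord]) -> pd.DataFrame:
    """Per habitat class: total item count, mean item volume and its SE.

    Items without a resolvable volume are excluded from the volume mean and
    reported in ``n_missing_volume``. Classes with no items report N = 0.
    """
    totals = {c: 0 for c in HABITAT_CLASSES}
    volumes: dict[str, list[float]] = {c: [] for c in HABITAT_CLASSES}
    missing = {c: 0 for c in HABITAT_CLASSES}
    for rec in records:
        if not rec.is_prey:
            continue
        totals[rec.habitat_class] += rec.count
        vol = rec.item_volume()
        if vol is None:
            missing[rec.habitat_class] += rec.count
        else:
            volumes[rec.habitat_class].extend([vol] * rec.count)
    rows = []
    for c in HABITAT_CLASSES:
        vols = np.asarray(volumes[c], dtype=float)
        mean = float(vols.mean()) if vols.size else float("nan")
        se = float(vols.std(ddof=1) / math.sqrt(vols.size)) if vols.size > 1 else float("nan")
        rows.append(
            {
                "habitat_class": c,
                "N": totals[c],
                "mean_volume_mm3": mean,
                "se_volume_mm3": se,
                "n_missing_volume": missing[c],
            }
        )
    return pd.DataFrame(rows).set_index("habitat_class")
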