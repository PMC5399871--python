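"""Domain types and tidy-CSV readers for stomach-content and availability data.

The common currency of the analysis is the :class:`AbundanceTable`: a
taxon-by-group matrix of item counts (N), summed item volumes (V, mm^3) and
occurrence frequencies (Freq, number of predators whose stomach contained the
taxon). Groups are strata such as ``"X_laevis|CoGH"`` or a pooled
``"environment|CoGH"`` sample.

Input data are tidy CSVs with one prey item (or one aggregated count of
identical items) per row, mirroring how stomach-flushing datasets are usually
recorded in the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPECIES: tuple[str, ...] = ("X_laevis", "X_gilli")
SITES_DEFAULT: tuple[str, ...] = ("CoGH", "Kleinmond")
SOURCES: tuple[str, ...] = ("stomach", "environment")
SAMPLING_METHODS: tuple[str, ...] = (
    "core",
    "sweep",
    "filter",
    "stomach_flush",
    "dissection",
)
HABITAT_CLASSES: tuple[str, ...] = ("benthos", "nekton", "zooplankton", "terrestrial")
DIGESTION_FLAGS: tuple[str, ...] = ("fresh", "partially_digested", "digested", "unknown")
NON_PREY_FLAGS: tuple[str, ...] = ("none", "sloughed_skin", "plant_matter", "stone")
SEXES: tuple[str, ...] = ("M", "F", "unknown")
ANURAN_CATEGORIES: tuple[str, ...] = (
    "tadpole_non_xenopus",
    "egg_non_xenopus",
    "adult_non_xenopus",
    "xenopus",
    "unknown",
)

#: Taxon label used for items too digested or fragmented to identify.
UNIDENTIFIED_TAXON = "Unidentified"

#: Taxa attracted into baited funnel traps; fresh (undigested) items of these
#: taxa may have been ingested inside the trap and can be dropped via a switch.
TRAP_ATTRACTED_TAXA: frozenset[str] = frozenset({"Anura"})

GROUP_SEP = "|"
ENVIRONMENT = "environment"


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class FormatError(ValueError):
    """An input file does not match the expected schema."""


def _check_vocab(value: str, vocab: Sequence[str], what: str) -> str:
    if value not in vocab:
        raise ValidationError(f"{what} {value!r} not in allowed vocabulary {sorted(vocab)}")
    return value


@dataclass
class PreyRecord:
    """One prey item (or an aggregated count of identical items).

    ``source`` is ``"stomach"`` for items recovered from a predator (then
    ``predator_id`` must be set) or ``"environment"`` for items from benthos
    core / nekton sweep / zooplankton filter sampling.
    """

    source: str
    site: str
    taxon: str
    habitat_class: str = "nekton"
    pond: str | None = None
    sampling_method: str | None = None
    predator_id: str | None = None
    count: int = 1
    length_mm: float | None = None
    width_mm: float | None = None
    height_mm: float | None = None
    volume_mm3: float | None = None
    digestion_flag: str = "unknown"
    non_prey_flag: str = "none"
    anuran_category: str | None = None

    def __post_init__(self) -> None:
        _check_vocab(self.source, SOURCES, "source")
        _check_vocab(self.habitat_class, HABITAT_CLASSES, "habitat_class")
        _check_vocab(self.digestion_flag, DIGESTION_FLAGS, "digestion_flag")
        _check_vocab(self.non_prey_flag, NON_PREY_FLAGS, "non_prey_flag")
        if self.sampling_method is not None:
            _check_vocab(self.sampling_method, SAMPLING_METHODS, "sampling_method")
        if self.anuran_category is not None:
            _check_vocab(self.anuran_category, ANURAN_CATEGORIES, "anuran_category")
        self.count = int(self.count)
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")
        for name in ("length_mm", "width_mm", "height_mm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.volume_mm3 is not None and self.volume_mm3 < 0:
            raise ValidationError(f"volume_mm3 must be >= 0, got {self.volume_mm3}")
        if self.source == "stomach" and self.predator_id is None:
            raise ValidationError("stomach record requires a predator_id")

    @property
    def is_prey(self) -> bool:
        """True unless the item is sloughed skin, plant matter or a stone."""
        return self.non_prey_flag == "none"

    def item_volume(self) -> float | None:
        """Volume of one item in mm^3, from ``volume_mm3`` or linear measures."""
        if self.volume_mm3 is not None:
            return self.volume_mm3
        if self.length_mm is not None and self.width_mm is not None:
            from .prey_metrics import ellipsoid_volume

            return ellipsoid_volume(self.length_mm, self.width_mm, self.height_mm)
        return None


@dataclass
class Predator:
    """One examined frog (stomach-flushed or dissected)."""

    predator_id: str
    species: str
    site: str
    svl_mm: float
    pond: str | None = None
    sex: str = "unknown"
    capture_date: str | None = None

    def __post_init__(self) -> None:
        _check_vocab(self.species, SPECIES, "species")
        _check_vocab(self.sex, SEXES, "sex")
        self.svl_mm = float(self.svl_mm)
        if not self.svl_mm > 0:
            raise ValidationError(f"svl_mm must be positive, got {self.svl_mm}")


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

_PREY_REQUIRED = ("source", "site", "taxon")
_PREDATOR_REQUIRED = ("predator_id", "species", "site", "svl_mm")


def _read_rows(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path.name}")
    return frame


def _opt(row: Mapping[str, str], key: str) -> str | None:
    v = row.get(key, "")
    return v if v not in ("", "NA", "nan") else None


def _opt_float(row: Mapping[str, str], key: str) -> float | None:
    v = _opt(row, key)
    return float(v) if v is not None else None


def read_prey_records(path: str | Path) -> list[PreyRecord]:
    """Read a tidy prey-records CSV (one item or aggregated count per row).

    Mandatory columns: ``source, site, taxon``. Counts default to 1. Rows that
    fail validation are collected and reported together with their line
    numbers (header = line 1).
    """
    frame = _read_rows(path, _PREY_REQUIRED)
    records: list[PreyRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header on line 1
        try:
            records.append(
                PreyRecord(
                    source=row["source"],
                    site=row["site"],
                    taxon=row["taxon"],
                    habitat_class=_opt(row, "habitat_class") or "nekton",
                    pond=_opt(row, "pond"),
                    sampling_method=_opt(row, "sampling_method"),
                    predator_id=_opt(row, "predator_id"),
                    count=int(_opt(row, "count") or 1),
                    length_mm=_opt_float(row, "length_mm"),
                    width_mm=_opt_float(row, "width_mm"),
                    height_mm=_opt_float(row, "height_mm"),
                    volume_mm3=_opt_float(row, "volume_mm3"),
                    digestion_flag=_opt(row, "digestion_flag") or "unknown",
                    non_prey_flag=_opt(row, "non_prey_flag") or "none",
                    anuran_category=_opt(row, "anuran_category"),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid row(s) in {Path(path).name}:\n" + "\n".join(errors)
        )
    return records


def read_predators(path: str | Path) -> list[Predator]:
    """Read a predators CSV (``predator_id, species, site, svl_mm`` + optional)."""
    frame = _read_rows(path, _PREDATOR_REQUIRED)
    predators: list[Predator] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2
        try:
            predators.append(
                Predator(
                    predator_id=row["predator_id"],
                    species=row["species"],
                    site=row["site"],
                    svl_mm=float(row["svl_mm"]),
                    pond=_opt(row, "pond"),
                    sex=_opt(row, "sex") or "unknown",
                    capture_date=_opt(row, "capture_date"),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid row(s) in {Path(path).name}:\n" + "\n".join(errors)
        )
    return predators


def write_prey_records(records: Iterable[PreyRecord], path: str | Path) -> None:
    cols = [f.name for f in fields(PreyRecord)]
    pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records]).to_csv(
        path, index=False
    )


def write_predators(predators: Iterable[Predator], path: str | Path) -> None:
    cols = [f.name for f in fields(Predator)]
    pd.DataFrame([{c: getattr(p, c) for c in cols} for p in predators]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# AbundanceTable
# ---------------------------------------------------------------------------

MEASURES = ("N", "V", "Freq")


def group_label(*parts: str) -> str:
    """Join stratum keys into a group label, e.g. ``X_gilli|CoGH|small``."""
    return GROUP_SEP.join(parts)


class AbundanceTable:
    """Taxon x group matrix of counts (N), volumes (V) and frequencies (Freq).

    Parameters
    ----------
    data:
        DataFrame indexed by taxon with a two-level column index
        ``(group, measure)`` where measure is one of ``N``, ``V``, ``Freq``.
    n_predators:
        Number of predators per stomach group (0 for environment groups).
    """

    def __init__(self, data: pd.DataFrame, n_predators: Mapping[str, int] | None = None):
        if not isinstance(data.columns, pd.MultiIndex):
            raise ValidationError("AbundanceTable needs (group, measure) columns")
        self.data = data.sort_index(axis=1, level=0, sort_remaining=False)
        self.n_predators = dict(n_predators or {})
        self.validate()

    # -- accessors ----------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def counts(self, group: str) -> pd.Series:
        return self.data[(group, "N")]

    def volumes(self, group: str) -> pd.Series:
        return self.data[(group, "V")]

    def freqs(self, group: str) -> pd.Series:
        return self.data[(group, "Freq")]

    def stomach_groups(self) -> list[str]:
        return [g for g in self.groups if not g.startswith(ENVIRONMENT)]

    def environment_groups(self) -> list[str]:
        return [g for g in self.groups if g.startswith(ENVIRONMENT)]

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate taxa in abundance table")
        for g in self.groups:
            n = self.counts(g)
            f = self.freqs(g)
            v = self.volumes(g)
            if (n < 0).any() or (f < 0).any() or (v < -1e-12).any():
                raise ValidationError(f"negative entries in group {g}")
            if not np.allclose(n, np.round(n)) or not np.allclose(f, np.round(f)):
                raise ValidationError(f"N and Freq must be integers in group {g}")
            cap = self.n_predators.get(g)
            if cap is not None and cap > 0 and (f > cap).any():
                raise ValidationError(f"Freq exceeds predator count in group {g}")

    # -- subsets and arithmetic --------------------------------------------
    def subset(self, groups: Sequence[str]) -> "AbundanceTable":
        cols = [c for c in self.data.columns if c[0] in groups]
        return AbundanceTable(
            self.data[cols].copy(),
            {g: n for g, n in self.n_predators.items() if g in groups},
        )

    # -- IO -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{g}:{m}" for g, m in flat.columns]
        flat.index.name = "taxon"
        header = "#n_predators " + ",".join(
            f"{g}={n}" for g, n in sorted(self.n_predators.items())
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            flat.to_csv(fh)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbundanceTable":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
            n_predators: dict[str, int] = {}
            if first.startswith("#n_predators"):
                body = first.split(None, 1)[1] if " " in first else ""
                for part in filter(None, body.split(",")):
                    g, n = part.split("=")
                    n_predators[g] = int(n)
                flat = pd.read_csv(fh, index_col="taxon")
            else:
                fh.seek(0)
                flat = pd.read_csv(fh, index_col="taxon")
        flat.columns = pd.MultiIndex.from_tuples(
            [tuple(c.rsplit(":", 1)) for c in flat.columns]
        )
        return cls(flat, n_predators)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AbundanceTable({len(self.taxa)} taxa x {len(self.groups)} groups: "
            f"{self.groups})"
        )


def table_from_arrays(
    taxa: Sequence[str],
    groups: Mapping[str, Mapping[str, Sequence[float]]],
    n_predators: Mapping[str, int] | None = None,
) -> AbundanceTable:
    """Build an :class:`AbundanceTable` from per-group N/V/Freq vectors.

    ``groups`` maps a group label to a dict with keys among ``N``, ``V``,
    ``Freq``; missing measures default to zero.
    """
    cols: dict[tuple[str, str], np.ndarray] = {}
    for g, measures in groups.items():
        for m in MEASURES:
            vec = np.asarray(measures.get(m, np.zeros(len(taxa))), dtype=float)
            if vec.shape != (len(taxa),):
                raise ValidationError(f"measure {m} for group {g} has wrong length")
            cols[(g, m)] = vec
    data = pd.DataFrame(cols, index=list(taxa))
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return AbundanceTable(data, n_predators)


def build_abundance_table(
    prey_records: Iterable[PreyRecord],
    predators: Iterable[Predator] | None = None,
    by: Sequence[str] = ("species", "site"),
    size_scheme=None,
    drop_trap_suspect: bool = False,
    trap_attracted: frozenset[str] = TRAP_ATTRACTED_TAXA,
) -> AbundanceTable:
    """Tally prey records into a taxon x group table of N, V and Freq.

    Stomach records are grouped by the keys in ``by`` (any of ``species``,
    ``site``, ``size_class``; ``size_class`` requires ``size_scheme``) looked
    up from their predator; environment records always form one pooled
    ``environment|<site>`` group per site. Non-prey items (sloughed skin,
    plant matter, stones) never enter the table. With ``drop_trap_suspect``,
    items of trap-attracted taxa showing no signs of digestion
    (``digestion_flag == "fresh"``) are excluded as possible in-trap ingestion.
    """
    from .pipeline import assign_size_class  # local import avoids a cycle

    predator_index: dict[str, Predator] = {
        p.predator_id: p for p in (predators or [])
    }

    def stomach_group(rec: PreyRecord) -> str:
        pred = predator_index.get(rec.predator_id)
        if pred is None:
            raise ValidationError(
                f"stomach record references unknown predator ID {rec.predator_id!r}"
            )
        parts = []
        for key in by:
            if key == "species":
                parts.append(pred.species)
            elif key == "site":
                parts.append(pred.site)
            elif key == "size_class":
                if size_scheme is None:
                    raise ValidationError("size_class grouping requires a size_scheme")
                parts.append(assign_size_class(pred.svl_mm, size_scheme))
            else:
                raise ValidationError(f"unknown grouping key {key!r}")
        return group_label(*parts)

    n_sum: dict[tuple[str, str], float] = {}
    v_sum: dict[tuple[str, str], float] = {}
    freq_sets: dict[tuple[str, str], set[str]] = {}
    taxa_order: list[str] = []
    group_order: list[str] = []

    for rec in prey_records:
        if not rec.is_prey:
            continue
        if (
            drop_trap_suspect
            and rec.source == "stomach"
            and rec.taxon in trap_attracted
            and rec.digestion_flag == "fresh"
        ):
            continue
        group = (
            group_label(ENVIRONMENT, rec.site)
            if rec.source == "environment"
            else stomach_group(rec)
        )
        key = (group, rec.taxon)
        if rec.taxon not in taxa_order:
            taxa_order.append(rec.taxon)
        if group not in group_order:
            group_order.append(group)
        n_sum[key] = n_sum.get(key, 0) + rec.count
        vol = rec.item_volume()
        if vol is not None:
            v_sum[key] = v_sum.get(key, 0.0) + vol * rec.count
        if rec.source == "stomach":
            freq_sets.setdefault(key, set()).add(rec.predator_id)

    groups: dict[str, dict[str, list[float]]] = {}
    for g in group_order:
        groups[g] = {
            "N": [n_sum.get((g, t), 0) for t in taxa_order],
            "V": [v_sum.get((g, t), 0.0) for t in taxa_order],
            "Freq": [len(freq_sets.get((g, t), ())) for t in taxa_order],
        }

    n_predators: dict[str, int] = {g: 0 for g in group_order}
    for pred in predator_index.values():
        try:
            g = stomach_group(
                PreyRecord(
                    source="stomach",
                    site=pred.site,
                    taxon="_",
                    predator_id=pred.predator_id,
                )
            )
        except ValidationError:
            continue
        if g in n_predators:
            n_predators[g] += 1
        else:
            n_predators[g] = 0 if g.startswith(ENVIRONMENT) else 1

    return table_from_arrays(taxa_order, groups, n_predators)
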