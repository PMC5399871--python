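"""Synthetic stomach-content and availability data with known ground truth.

Emulates the sampling design of a two-site, two-species stomach-flushing
study: pooled semi-quantitative environmental samples (benthos cores, nekton
sweeps, zooplankton filters) and per-predator stomach contents. Environmental
counts are multinomial draws from a site's availability distribution; stomach
item totals are negative-binomial (overdispersed, mimicking the few stomachs
that dominate counts of swarming prey) with taxa drawn multinomially from the
group's true utilization distribution. Empty stomachs and non-prey
contamination (sloughed skin, plant matter, stones) are injected at
configurable rates.

Because the generating distributions are known exactly, every estimator in
the package can be checked for parameter recovery: estimated profiles, the
overlap of estimated profiles against the overlap of the true distributions,
electivity around zero when diet tracks availability, and null-model
calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import datasets
from .core_data import (
    ENVIRONMENT,
    Predator,
    PreyRecord,
    ValidationError,
    group_label,
    write_predators,
    write_prey_records,
)
from .overlap import pianka_overlap

_METHOD_OF_CLASS = {
    "benthos": "core",
    "nekton": "sweep",
    "zooplankton": "filter",
    "terrestrial": "sweep",
}

#: generic log-normal (mean-log, sd-log) of prey length and width in mm
_DEFAULT_SIZE = (1.2, 0.6, 0.2, 0.5)


@dataclass
class CommunityConfig:
    """Ground truth for a synthetic two-species, multi-site community.

    ``availability[site]`` and ``utilization[(site, species)]`` are proportion
    vectors over ``taxa``. ``items_mean`` is the expected number of prey items
    per non-empty stomach (scalar, or per (site, species));
    ``items_dispersion`` is the negative-binomial size parameter k (smaller =
    more overdispersed). ``svl_norm[species]`` gives the (mean, sd) of the
    SVL distribution, truncated at ``svl_min``.
    """

    taxa: tuple[str, ...]
    habitat_of: dict
    availability: dict
    utilization: dict
    n_predators: dict
    env_total: dict | int = 2000
    items_mean: dict | float = 12.0
    items_dispersion: float = 0.8
    size_lognormal: dict = field(default_factory=dict)
    svl_norm: dict = field(
        default_factory=lambda: {"X_laevis": (62.0, 14.0), "X_gilli": (45.0, 8.0)}
    )
    svl_min: float = 30.0
    frac_empty: float = 0.05
    contamination: dict = field(
        default_factory=lambda: {
            "sloughed_skin": 0.15,
            "plant_matter": 0.14,
            "stone": 0.01,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for site, vec in self.availability.items():
            self.availability[site] = _valid_dist(vec, len(self.taxa), f"availability[{site}]")
        for key, vec in self.utilization.items():
            self.utilization[key] = _valid_dist(vec, len(self.taxa), f"utilization[{key}]")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.availability)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({sp for _, sp in self.utilization}))

    def mean_items(self, site: str, species: str) -> float:
        if isinstance(self.items_mean, dict):
            return float(self.items_mean[(site, species)])
        return float(self.items_mean)


def _valid_dist(vec, k: int, what: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (k,):
        raise ValidationError(f"{what} has length {vec.size}, expected {k}")
    if (vec < 0).any() or vec.sum() <= 0:
        raise ValidationError(f"{what} is not a valid distribution")
    return vec / vec.sum()


def paper_like_config(seed: int = 0) -> CommunityConfig:
    """A community statistically resembling the packaged study tables.

    Availability and utilization vectors equal the observed proportions at
    each site; predator numbers and environmental totals match the study;
    mean items per stomach equals each group's observed items-per-predator.
    """
    taxa = sorted(set(datasets.COGH) | set(datasets.KLEINMOND))
    availability = {}
    utilization = {}
    env_total = {}
    items_mean = {}
    n_predators = {}
    for site, rows in (("CoGH", datasets.COGH), ("Kleinmond", datasets.KLEINMOND)):
        ne = np.array([rows.get(t, (0,))[0] for t in taxa], dtype=float)
        availability[site] = ne / ne.sum()
        env_total[site] = int(ne.sum())
        for species, col in (("X_laevis", 2), ("X_gilli", 5)):
            n = np.array(
                [rows[t][col] if t in rows else 0 for t in taxa], dtype=float
            )
            utilization[(site, species)] = n / n.sum()
            n_pred = datasets.N_PREDATORS[(site, species)]
            n_predators[(site, species)] = n_pred
            items_mean[(site, species)] = float(n.sum() / n_pred)
    return CommunityConfig(
        taxa=tuple(taxa),
        habitat_of=dict(datasets.HABITAT_OF),
        availability=availability,
        utilization=utilization,
        n_predators=n_predators,
        env_total=env_total,
        items_mean=items_mean,
        seed=seed,
    )


def _draw_measures(config: CommunityConfig, taxon: str, rng) -> tuple[float, float]:
    ml, sl, mw, sw = config.size_lognormal.get(taxon, _DEFAULT_SIZE)
    return float(rng.lognormal(ml, sl)), float(rng.lognormal(mw, sw))


def generate_environment(
    config: CommunityConfig,
    site: str,
    rng: np.random.Generator | None = None,
    total: int | None = None,
) -> list[PreyRecord]:
    """Pooled environmental sample for one site: one record per prey item."""
    if site not in config.availability:
        raise ValidationError(f"site {site!r} not in config")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if total is None:
        total = (
            config.env_total[site]
            if isinstance(config.env_total, dict)
            else config.env_total
        )
    counts = rng.multinomial(total, config.availability[site])
    records = []
    for taxon, count in zip(config.taxa, counts):
        habitat = config.habitat_of.get(taxon, "nekton")
        for _ in range(int(count)):
            length, width = _draw_measures(config, taxon, rng)
            records.append(
                PreyRecord(
                    source="environment",
                    site=site,
                    taxon=taxon,
                    habitat_class=habitat,
                    sampling_method=_METHOD_OF_CLASS[habitat],
                    count=1,
                    length_mm=length,
                    width_mm=width,
                )
            )
    return records


def generate_stomachs(
    config: CommunityConfig,
    site: str,
    species: str,
    rng: np.random.Generator | None = None,
) -> tuple[list[Predator], list[PreyRecord]]:
    """Predators and their stomach contents for one (site, species) group."""
    key = (site, species)
    if key not in config.utilization:
        raise ValidationError(f"group {key} not in config")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    util = config.utilization[key]
    mean = config.mean_items(site, species)
    k = config.items_dispersion
    n_pred = int(config.n_predators.get(key, 0))

    predators: list[Predator] = []
    records: list[PreyRecord] = []
    mu, sd = config.svl_norm.get(species, (55.0, 12.0))
    for i in range(n_pred):
        pid = f"{species}-{site}-{i:04d}"
        svl = 0.0
        while svl < config.svl_min:
            svl = rng.normal(mu, sd)
        predators.append(
            Predator(
                predator_id=pid,
                species=species,
                site=site,
                svl_mm=round(float(svl), 1),
                sex=str(rng.choice(["M", "F"])),
            )
        )
        if rng.uniform() < config.frac_empty:
            n_items = 0
        else:
            # NB(k, p) with mean k(1-p)/p = `mean`; at least one item
            n_items = 1 + int(rng.negative_binomial(k, k / (k + mean)))
        if n_items > 0:
            taxon_counts = rng.multinomial(n_items, util)
            for taxon, count in zip(config.taxa, taxon_counts):
                if count == 0:
                    continue
                length, width = _draw_measures(config, taxon, rng)
                records.append(
                    PreyRecord(
                        source="stomach",
                        site=site,
                        taxon=taxon,
                        habitat_class=config.habitat_of.get(taxon, "nekton"),
                        sampling_method="stomach_flush",
                        predator_id=pid,
                        count=int(count),
                        length_mm=length,
                        width_mm=width,
                        digestion_flag=str(
                            rng.choice(["partially_digested", "digested"])
                        ),
                        anuran_category=(
                            "tadpole_non_xenopus" if taxon.startswith("Anura") else None
                        ),
                    )
                )
        for flag, rate in config.contamination.items():
            if rng.uniform() < rate:
                records.append(
                    PreyRecord(
                        source="stomach",
                        site=site,
                        taxon=flag,
                        habitat_class="terrestrial",
                        sampling_method="stomach_flush",
                        predator_id=pid,
                        count=1,
                        non_prey_flag=flag,
                    )
                )
    return predators, records


def generate_study(
    config: CommunityConfig, seed: int | None = None
) -> tuple[list[PreyRecord], list[Predator], dict]:
    """Full synthetic dataset plus a ground-truth dictionary.

    Truth holds the generating availability and utilization proportions and
    the pairwise overlap of the true utilization distributions per site.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[PreyRecord] = []
    predators: list[Predator] = []
    for site in config.sites:
        records.extend(generate_environment(config, site, rng))
        for species in config.species:
            if (site, species) in config.utilization:
                preds, recs = generate_stomachs(config, site, species, rng)
                predators.extend(preds)
                records.extend(recs)

    truth: dict = {"availability": {}, "utilization": {}, "overlap": {}}
    for site in config.sites:
        truth["availability"][site] = dict(
            zip(config.taxa, map(float, config.availability[site]))
        )
        sps = [sp for sp in config.species if (site, sp) in config.utilization]
        for sp in sps:
            truth["utilization"][group_label(sp, site)] = dict(
                zip(config.taxa, map(float, config.utilization[(site, sp)]))
            )
        if len(sps) == 2:
            truth["overlap"][site] = pianka_overlap(
                config.utilization[(site, sps[0])], config.utilization[(site, sps[1])]
            )
    return records, predators, truth


def write_dataset(config: CommunityConfig, outdir: str | Path, seed: int | None = None):
    """Write prey-records CSV, predators CSV and truth JSON for a study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, predators, truth = generate_study(config, seed)
    write_prey_records(records, outdir / "prey_records.csv")
    write_predators(predators, outdir / "predators.csv")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return records, predators, truth
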