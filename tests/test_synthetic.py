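"""Synthetic-data generator: determinism, calibration, parameter recovery."""

import numpy as np
import pytest

from preyniche.core_data import build_abundance_table, group_label
from preyniche.electivity import selection_analysis
from preyniche.overlap import pianka_overlap
from preyniche.prey_metrics import make_profile
from preyniche.synthetic import (
    CommunityConfig,
    generate_environment,
    generate_stomachs,
    generate_study,
    paper_like_config,
)


def _tiny_config(**kw):
    base = dict(
        taxa=("A", "B", "C"),
        habitat_of={"A": "benthos", "B": "nekton", "C": "zooplankton"},
        availability={"S": np.array([0.5, 0.3, 0.2])},
        utilization={("S", "X_laevis"): np.array([0.2, 0.5, 0.3]),
                     ("S", "X_gilli"): np.array([0.6, 0.2, 0.2])},
        n_predators={("S", "X_laevis"): 30, ("S", "X_gilli"): 30},
        env_total=500,
        items_mean=20.0,
        frac_empty=0.0,
        contamination={},
        seed=0,
    )
    base.update(kw)
    return CommunityConfig(**base)


class TestEnvironment:
    def test_degenerate_availability_yields_single_taxon(self):
        cfg = _tiny_config(availability={"S": np.array([1.0, 0.0, 0.0])})
        records = generate_environment(cfg, "S")
        assert {r.taxon for r in records} == {"A"}

    def test_empirical_proportions_within_three_se(self, rng):
        cfg = _tiny_config(env_total=2873)
        records = generate_environment(cfg, "S", rng=rng)
        counts = {t: 0 for t in cfg.taxa}
        for r in records:
            counts[r.taxon] += r.count
        n = sum(counts.values())
        assert n == 2873
        for t, p in zip(cfg.taxa, cfg.availability["S"]):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[t] / n - p) < 3 * se + 1e-12

    def test_fixed_seed_reproduces_dataset(self):
        cfg = _tiny_config(seed=99)
        r1, p1, t1 = generate_study(cfg)
        r2, p2, t2 = generate_study(cfg)
        assert r1 == r2 and p1 == p2 and t1 == t2

    def test_sampling_method_follows_habitat_class(self):
        cfg = _tiny_config()
        for r in generate_environment(cfg, "S"):
            expected = {"benthos": "core", "nekton": "sweep",
                        "zooplankton": "filter"}[r.habitat_class]
            assert r.sampling_method == expected


class TestStomachs:
    def test_taxon_totals_within_three_se(self, rng):
        cfg = _tiny_config(
            utilization={("S", "X_laevis"): np.array([0.5, 0.5, 0.0]),
                         ("S", "X_gilli"): np.array([0.5, 0.5, 0.0])},
            n_predators={("S", "X_laevis"): 100, ("S", "X_gilli"): 0},
            items_mean=10.0,
            items_dispersion=5.0,
        )
        _, records = generate_stomachs(cfg, "S", "X_laevis", rng=rng)
        totals = {"A": 0, "B": 0, "C": 0}
        n = 0
        for r in records:
            totals[r.taxon] += r.count
            n += r.count
        assert totals["C"] == 0
        se = np.sqrt(0.25 * n)
        assert abs(totals["A"] - n / 2) < 3 * se

    def test_zero_predators_yield_empty_but_valid_output(self):
        cfg = _tiny_config(n_predators={("S", "X_laevis"): 0, ("S", "X_gilli"): 0})
        predators, records = generate_stomachs(cfg, "S", "X_laevis")
        assert predators == [] and records == []

    def test_contamination_flagged_non_prey(self, rng):
        cfg = _tiny_config(contamination={"plant_matter": 1.0})
        _, records = generate_stomachs(cfg, "S", "X_laevis", rng=rng)
        flags = [r for r in records if r.non_prey_flag == "plant_matter"]
        assert len(flags) == 30  # one per predator at rate 1.0
        assert all(not r.is_prey for r in flags)

    def test_anurophagy_tracks_planted_concentration(self, rng):
        cfg = _tiny_config(
            taxa=("Anura", "Acari"),
            habitat_of={"Anura": "nekton", "Acari": "benthos"},
            availability={"S": np.array([0.5, 0.5])},
            utilization={("S", "X_laevis"): np.array([0.7, 0.3]),
                         ("S", "X_gilli"): np.array([0.7, 0.3])},
        )
        from preyniche.pipeline import anurophagy_summary

        predators, records = generate_stomachs(cfg, "S", "X_laevis", rng=rng)
        table = build_abundance_table(records, predators)
        s = anurophagy_summary(table, group_label("X_laevis", "S"))
        assert s.ratio == pytest.approx(0.7, abs=0.05)


class TestParameterRecovery:
    def test_overlap_estimate_converges_with_sample_size(self):
        cfg = _tiny_config()
        true_overlap = pianka_overlap(
            cfg.utilization[("S", "X_laevis")], cfg.utilization[("S", "X_gilli")]
        )
        errors = []
        for n_pred, seed in ((10, 1), (100, 1), (1000, 1)):
            c = _tiny_config(
                n_predators={("S", "X_laevis"): n_pred, ("S", "X_gilli"): n_pred},
                items_mean=10.0,
                seed=seed,
            )
            records, predators, _ = generate_study(c)
            table = build_abundance_table(
                [r for r in records if r.source == "stomach"], predators
            )
            est = pianka_overlap(
                make_profile(table, group_label("X_laevis", "S")),
                make_profile(table, group_label("X_gilli", "S")),
            )
            errors.append(abs(est - true_overlap))
        assert errors[2] < errors[0]
        assert errors[2] < 0.02

    def test_truth_json_matches_generating_distributions(self):
        cfg = _tiny_config()
        _, _, truth = generate_study(cfg)
        assert truth["overlap"]["S"] == pytest.approx(
            pianka_overlap(cfg.utilization[("S", "X_laevis")],
                           cfg.utilization[("S", "X_gilli")])
        )
        assert truth["availability"]["S"]["A"] == pytest.approx(0.5)

    def test_no_selection_gives_near_zero_electivity(self):
        avail = np.array([0.4, 0.35, 0.25])
        cfg = _tiny_config(
            availability={"S": avail},
            utilization={("S", "X_laevis"): avail, ("S", "X_gilli"): avail},
            n_predators={("S", "X_laevis"): 150, ("S", "X_gilli"): 150},
            env_total=5000,
            items_mean=15.0,
            seed=21,
        )
        records, predators, _ = generate_study(cfg)
        table = build_abundance_table(records, predators)
        res = selection_analysis(table, group_label("X_laevis", "S"), min_total=10)
        estars = res.per_taxon["estar"].dropna()
        assert abs(estars.mean()) < 0.1

    def test_planted_preference_detected(self):
        avail = np.array([0.1, 0.45, 0.45])
        util = np.array([0.6, 0.2, 0.2])  # strong preference for taxon A
        cfg = _tiny_config(
            availability={"S": avail},
            utilization={("S", "X_laevis"): util, ("S", "X_gilli"): util},
            n_predators={("S", "X_laevis"): 100, ("S", "X_gilli"): 100},
            env_total=5000,
            items_mean=15.0,
            seed=33,
        )
        records, predators, _ = generate_study(cfg)
        table = build_abundance_table(records, predators)
        res = selection_analysis(table, group_label("X_laevis", "S"))
        row = res.per_taxon.loc["A"]
        assert row["estar"] > 0.5
        assert row["verdict"] == "preferred"
        assert res.chi2.pvalue < 1e-6

    def test_paper_like_config_matches_study_design(self):
        cfg = paper_like_config(seed=0)
        assert set(cfg.sites) == {"CoGH", "Kleinmond"}
        assert cfg.n_predators[("CoGH", "X_laevis")] == 94
        assert cfg.env_total["CoGH"] == 2873
        # utilization concentrates on Anura for Kleinmond X. laevis
        i = cfg.taxa.index("Anura")
        assert cfg.utilization[("Kleinmond", "X_laevis")][i] == pytest.approx(
            1131 / 1680
        )
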