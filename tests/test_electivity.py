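"""Electivity index, inclusion rule, chi-square test and Bonferroni intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from preyniche import datasets
from preyniche.core_data import ValidationError
from preyniche.electivity import (
    bonferroni_intervals,
    chisq_selection_test,
    electivity_index,
    inclusion_mask,
    round_half_up,
    selection_analysis,
)

props = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
open_props = st.floats(min_value=1e-6, max_value=1 - 1e-6)


class TestElectivityIndex:
    def test_proportional_use_is_zero(self):
        assert electivity_index(0.3, 0.3) == 0.0

    def test_total_avoidance_and_exclusive_preference(self):
        assert electivity_index(0.0, 0.2) == -1.0
        assert electivity_index(0.2, 0.0) == 1.0

    def test_undefined_when_both_zero(self):
        assert math.isnan(electivity_index(0.0, 0.0))

    @pytest.mark.parametrize(
        "site,species,taxon,expected",
        [
            ("CoGH", "X_laevis", "Ostracoda", 0.91),
            ("CoGH", "X_laevis", "Coleoptera", 0.73),
            ("CoGH", "X_laevis", "Acari", 0.94),
            ("CoGH", "X_laevis", "Zygoptera", -0.99),
            ("CoGH", "X_gilli", "Amphipoda", 0.99),
            ("Kleinmond", "X_laevis", "Daphnia", 1.00),
        ],
    )
    def test_worked_examples_from_study_tables(self, site, species, taxon, expected):
        r = datasets.diet_profile(site, species)[taxon]
        p = datasets.availability_profile(site)[taxon]
        assert round_half_up(electivity_index(r, p), 2) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(r=props, p=props)
    def test_bounds_and_sign(self, r, p):
        e = electivity_index(r, p)
        if math.isnan(e):
            assert r == 0 and p == 0
        else:
            assert -1 <= e <= 1
            assert np.sign(e) == np.sign(r - p)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(r=props, p=props)
    def test_antisymmetry(self, r, p):
        e1, e2 = electivity_index(r, p), electivity_index(p, r)
        if not math.isnan(e1):
            assert e1 == pytest.approx(-e2, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(p=open_props, r1=open_props, r2=open_props)
    def test_strictly_increasing_in_diet_proportion(self, p, r1, r2):
        lo, hi = sorted((r1, r2))
        if hi - lo > 1e-9:
            assert electivity_index(hi, p) > electivity_index(lo, p)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            electivity_index(1.2, 0.5)


class TestInclusionRule:
    def test_low_total_taxon_excluded(self, kleinmond_table):
        mask = inclusion_mask(kleinmond_table, min_total=10)
        assert not mask["Trichoptera"]  # 3 + 6 = 9 items across both species

    def test_shared_total_clears_threshold(self, cogh_table):
        mask = inclusion_mask(cogh_table, min_total=10)
        assert mask["Coleoptera"]  # 20 + 30 = 50

    def test_zero_threshold_includes_everything(self, cogh_table):
        assert inclusion_mask(cogh_table, min_total=0).all()

    def test_threshold_basis_is_configurable(self, cogh_table):
        # Heteroptera: Freq 8+1=9 but N 15+1=16, so the basis matters
        assert not inclusion_mask(cogh_table, 10, "freq")["Heteroptera"]
        assert inclusion_mask(cogh_table, 10, "count")["Heteroptera"]


class TestChiSquare:
    def test_proportional_observation_gives_zero(self):
        res = chisq_selection_test([30, 20, 50], [0.3, 0.2, 0.5])
        assert res.statistic == pytest.approx(0.0)
        np.testing.assert_allclose(res.residuals, 0.0)

    def test_two_cell_closed_form(self):
        res = chisq_selection_test([10, 0], [0.5, 0.5])
        assert res.statistic == pytest.approx(10.0)
        np.testing.assert_allclose(res.residuals, [math.sqrt(5), -math.sqrt(5)])
        assert res.df == 1

    def test_matches_textbook_formula(self, rng):
        for _ in range(10):
            obs = rng.integers(1, 200, size=5).astype(float)
            p = rng.dirichlet(np.ones(5))
            res = chisq_selection_test(obs, p)
            exp = obs.sum() * p
            assert res.statistic == pytest.approx(
                np.sum((obs - exp) ** 2 / exp), abs=1e-10
            )
            assert res.pvalue == pytest.approx(
                stats.chi2.sf(res.statistic, 4), abs=1e-12
            )

    def test_statistic_is_sum_of_squared_residuals_and_order_invariant(self, rng):
        obs = np.array([12.0, 40.0, 8.0, 30.0])
        p = np.array([0.2, 0.4, 0.1, 0.3])
        res = chisq_selection_test(obs, p)
        assert res.statistic == pytest.approx(np.sum(res.residuals**2))
        perm = rng.permutation(4)
        res2 = chisq_selection_test(obs[perm], p[perm])
        assert res2.statistic == pytest.approx(res.statistic)

    def test_zero_availability_taxon_dropped(self):
        res = chisq_selection_test([5, 10], [0.0, 1.0], taxa=["A", "B"])
        assert res.dropped == ("A",)
        assert res.taxa == ("B",)


class TestBonferroni:
    def test_half_width_matches_normal_quantile(self):
        ci = bonferroni_intervals(pd.Series({"A": 50, "B": 50}), alpha=0.05)
        z = stats.norm.ppf(1 - 0.05 / 4)
        half = z * math.sqrt(0.25 / 100)
        assert z == pytest.approx(2.2414, abs=1e-4)
        assert ci.loc["A", "ci_high"] - ci.loc["A", "p_hat"] == pytest.approx(half)
        assert half == pytest.approx(0.1121, abs=1e-4)

    def test_zero_count_gives_degenerate_interval(self):
        ci = bonferroni_intervals(pd.Series({"A": 0, "B": 20}))
        assert ci.loc["A", "ci_low"] == 0.0 and ci.loc["A", "ci_high"] == 0.0

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            bonferroni_intervals(pd.Series(dtype=float))


class TestSelectionAnalysis:
    def test_full_report_structure(self, cogh_table):
        res = selection_analysis(cogh_table, "X_laevis|CoGH")
        tab = res.per_taxon
        assert set(tab.columns) >= {
            "r", "p", "estar", "included", "residual", "ci_low", "ci_high", "verdict"
        }
        # E* only for included taxa
        assert tab.loc[~tab["included"], "estar"].isna().all()
        # taxon eaten but absent from the environment reports E* = +1
        assert tab.loc["Hymenoptera", "estar"] == 1.0
        assert res.chi2 is not None
        assert res.chi2.statistic == pytest.approx(np.sum(res.chi2.residuals**2))

    def test_verdicts_follow_intervals(self, cogh_table):
        res = selection_analysis(cogh_table, "X_laevis|CoGH")
        tab = res.per_taxon
        strong = tab.loc["Ostracoda"]
        assert strong["verdict"] == "preferred"
        avoided = tab.loc["Zygoptera"]
        assert avoided["verdict"] == "avoided"

    def test_proportional_when_availability_inside_every_interval(self):
        from preyniche.core_data import table_from_arrays

        taxa = ["A", "B"]
        table = table_from_arrays(
            taxa,
            {
                "environment|S": {"N": [50, 50]},
                "X_laevis|S": {"N": [51, 49], "Freq": [10, 10]},
            },
            {"X_laevis|S": 12, "environment|S": 0},
        )
        res = selection_analysis(table, "X_laevis|S")
        assert (res.per_taxon["verdict"] == "proportional").all()


def test_round_half_up_matches_report_convention():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(-0.125, 2) == -0.13
    assert round_half_up(0.905, 2) == 0.91
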