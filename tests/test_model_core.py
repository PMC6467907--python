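"""Unit and property tests for the core model equations and classifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breederinvest import (
    Category,
    DegenerateBroodError,
    DomainError,
    InvalidInputError,
    ModelParams,
    apply_singleton_rule,
    brood_profile,
    category_for,
    classify,
    convergent_index,
    gini,
    gini_rank_form,
    map_to_legacy,
    predation_mortality,
    relative_quality,
    summarize_by_taxon,
)

from conftest import gini_pairwise, make_record

TOL = 1e-12

positive_masses = st.lists(
    st.floats(min_value=1e-3, max_value=1e6, allow_nan=False),
    min_size=2, max_size=50,
)
distinct_masses = st.lists(
    st.floats(min_value=1e-3, max_value=1e6, allow_nan=False),
    min_size=2, max_size=50, unique=True,
)


class TestPredationMortality:
    @pytest.mark.parametrize(
        "n, w, expected",
        [(20, 2, 0.9), (2, 2, 0.0), (2.1, 2, 1 - 2 / 2.1), (1000, 2, 0.998)],
    )
    def test_values(self, n, w, expected):
        assert predation_mortality(n, w) == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize("n, w", [(0, 2), (-1, 2), (5, 0), (5, -2)])
    def test_nonpositive_inputs_rejected(self, n, w):
        with pytest.raises(InvalidInputError):
            predation_mortality(n, w)

    def test_brood_below_replacement_is_domain_error_not_clamped(self):
        with pytest.raises(DomainError, match="singleton"):
            predation_mortality(1, 2)

    @given(st.floats(min_value=2.0, max_value=1e9, exclude_min=True))
    def test_strictly_increasing_in_n(self, n):
        assert predation_mortality(n * 1.5, 2.0) > predation_mortality(n, 2.0)


class TestRelativeQuality:
    @pytest.mark.parametrize("m, M, expected", [(5, 100, 0.05), (0, 10, 0.0), (10, 10, 1.0)])
    def test_values(self, m, M, expected):
        assert relative_quality(m, M) == expected

    def test_offspring_heavier_than_breeder_allowed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert relative_quality(12, 10) == pytest.approx(1.2)
        assert any("exceeds 1" in r.message for r in caplog.records)

    @pytest.mark.parametrize("m, M", [(5, 0), (5, -1), (-1, 10)])
    def test_invalid_masses_rejected(self, m, M):
        with pytest.raises(InvalidInputError):
            relative_quality(m, M)

    @given(st.floats(min_value=0.0, max_value=1e6), st.floats(min_value=1e-3, max_value=1e6))
    def test_strictly_increasing_in_offspring_mass(self, m, M):
        assert relative_quality(m + 1.0, M) > relative_quality(m, M)


class TestGini:
    def test_equal_brood_is_exactly_zero(self):
        assert gini([1.0] * 10) == 0.0
        assert gini_rank_form([1.0] * 10) == 0.0

    def test_one_owner_brood_is_exactly_one(self):
        masses = [1.0] + [0.0] * 9
        assert gini(masses) == 1.0
        assert gini_rank_form(masses) == 1.0

    def test_three_offspring_example_matches_pairwise_oracle(self):
        assert gini([3, 2, 1]) == pytest.approx(gini_pairwise([3, 2, 1]), abs=TOL)
        assert gini([3, 2, 1]) == pytest.approx(1 / 3, abs=TOL)

    @pytest.mark.parametrize("bad", [[1.0], [], [1.0, -0.5], [1.0, math.nan]])
    def test_invalid_broods_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            gini(bad)

    def test_all_zero_brood_is_degenerate(self):
        with pytest.raises(DegenerateBroodError):
            gini([0.0, 0.0, 0.0])

    @settings(max_examples=200, deadline=None)
    @given(positive_masses)
    def test_matches_pairwise_oracle(self, masses):
        assert gini(masses) == pytest.approx(gini_pairwise(masses), abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(distinct_masses)
    def test_rank_form_agrees_for_distinct_masses(self, masses):
        assert gini(masses) == pytest.approx(gini_rank_form(masses), abs=TOL)

    @settings(max_examples=100, deadline=None)
    @given(positive_masses, st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_permutation_and_scaling(self, masses, c):
        g = gini(masses)
        assert gini(masses[::-1]) == pytest.approx(g, abs=TOL)
        assert gini([c * m for m in masses]) == pytest.approx(g, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(positive_masses)
    def test_bounded_between_zero_and_one(self, masses):
        assert -TOL <= gini(masses) <= 1 + TOL

    def test_brood_profile_ranks_descend_with_mass(self):
        profile = brood_profile([2.0, 5.0, 1.0, 3.0])
        assert profile.ranks == (3, 1, 4, 2)
        assert profile.mu == pytest.approx(2.75)
        assert sorted(profile.ranks) == [1, 2, 3, 4]


class TestConvergentIndex:
    @pytest.mark.parametrize("p, s, expected", [(0.9, 0.5, 0.45), (0.0, 0.7, 0.0), (1.0, 1.0, 1.0)])
    def test_values(self, p, s, expected):
        assert convergent_index(p, s) == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize("p, s", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 1.5)])
    def test_out_of_range_rejected(self, p, s):
        with pytest.raises(InvalidInputError):
            convergent_index(p, s)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_nondecreasing_in_each_factor(self, p, s, bump):
        hi = min(1.0, p + bump)
        assert convergent_index(hi, s) >= convergent_index(p, s)
        hi_s = min(1.0, s + bump)
        assert convergent_index(p, hi_s) >= convergent_index(p, s)


class TestSingletonRule:
    def test_singleton_brood_substituted_and_flagged(self, params):
        assert apply_singleton_rule(1, params) == (2.1, True)

    @pytest.mark.parametrize("n", [50, 2, 2.0])
    def test_rule_inactive_at_or_above_replacement(self, n, params):
        assert apply_singleton_rule(n, params) == (float(n), False)

    def test_fractional_brood_below_replacement_substituted(self, params):
        effective, applied = apply_singleton_rule(1.5, params)
        assert (effective, applied) == (2.1, True)

    def test_substitution_yields_positive_mortality(self, params):
        effective, _ = apply_singleton_rule(1, params)
        assert predation_mortality(effective, params.w) > 0

    def test_nonpositive_brood_rejected(self, params):
        with pytest.raises(InvalidInputError):
            apply_singleton_rule(0, params)


class TestParams:
    def test_defaults(self, params):
        assert (params.w, params.s_setpoint, params.n_setpoint, params.n_substitute) == (
            2.0, 0.1, 10.0, 2.1,
        )

    @pytest.mark.parametrize(
        "kwargs",
        [dict(w=0), dict(n_substitute=1.9), dict(s_setpoint=0), dict(n_setpoint=0.5)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            ModelParams(**kwargs)


class TestClassify:
    @pytest.mark.parametrize(
        "s, n, expected",
        [
            (0.05, 100, Category.PREDATION),
            (0.5, 2.1, Category.SCARCITY),
            (0.1, 10, Category.WEAK),  # both boundaries are inclusive on the low side
            (0.3, 500, Category.CONVERGENT),
            (0.1 + 1e-9, 10, Category.SCARCITY),
            (0.1, 10 + 1e-9, Category.PREDATION),
        ],
    )
    def test_quadrant_assignment(self, s, n, expected, params):
        assert classify(make_record(s, n), params).category is expected

    def test_singleton_species_classified_by_effective_n(self, params):
        result = classify(make_record(0.5, 1.0), params)
        assert result.singleton_rule_applied
        assert result.effective_n == 2.1
        assert result.category is Category.SCARCITY
        assert result.p_value == pytest.approx(1 - 2 / 2.1, abs=TOL)

    def test_c_and_g_attached(self, params):
        result = classify(make_record(0.5, 20, brood=(3.0, 2.0, 1.0)), params)
        assert result.c_value == pytest.approx(result.p_value * result.s_value, abs=TOL)
        assert result.g_value == pytest.approx(1 / 3, abs=TOL)

    def test_g_absent_without_brood_masses(self, params):
        assert classify(make_record(0.5, 20), params).g_value is None

    @settings(max_examples=300, deadline=None)
    @given(
        st.floats(min_value=1e-6, max_value=10.0),
        st.floats(min_value=1e-3, max_value=1e7),
    )
    def test_partition_exactly_one_category(self, s, n):
        params = ModelParams()
        low_s, low_n = s <= params.s_setpoint, n <= params.n_setpoint
        regions = [
            low_s and not low_n,        # predation
            not low_s and low_n,        # scarcity
            low_s and low_n,            # weak
            not low_s and not low_n,    # convergent
        ]
        assert sum(regions) == 1
        expected = [
            Category.PREDATION, Category.SCARCITY, Category.WEAK, Category.CONVERGENT
        ][regions.index(True)]
        assert category_for(s, n, params) is expected


class TestLegacyMapping:
    @pytest.mark.parametrize(
        "category, expected",
        [
            (Category.SCARCITY, ("r-selection", "S-selection")),
            (Category.WEAK, ("K-selection", "C-selection")),
            (Category.PREDATION, (None, "R-selection")),
            (Category.CONVERGENT, (None, None)),
        ],
    )
    def test_counterparts(self, category, expected):
        assert map_to_legacy(category) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(InvalidInputError):
            map_to_legacy("apex")


class TestSummarizeByTaxon:
    def test_counts_and_row_sums(self, params):
        results = [
            classify(make_record(0.01, 100, name=f"f{i}", taxon="fish"), params)
            for i in range(3)
        ]
        results += [
            classify(make_record(0.5, 3, name="b1", taxon="bird"), params),
            classify(make_record(0.5, 4, name="b2", taxon="bird"), params),
            classify(make_record(0.05, 4, name="b3", taxon="bird"), params),
        ]
        table = summarize_by_taxon(results)
        assert table.loc["fish", "predation"] == 3
        assert table.loc["bird"].sum() == 3
        assert table.loc["bird", "scarcity"] == 2
        assert table.loc["bird", "weak"] == 1
        assert list(table.columns) == ["predation", "scarcity", "weak", "convergent"]
        assert int(table.to_numpy().sum()) == 6

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_by_taxon([])
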