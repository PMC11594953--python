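"""Cross-tabulation, agreement, and 2x2 contingency statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from selfmanhf import (
    ContingencyTable2x2,
    ValidationError,
    category_distribution_stats,
    concordance_proportion,
    crosstab,
    exact_test_2x2,
    pearson_chi2_2x2,
)

categories = st.integers(min_value=0, max_value=3)
cat_lists = st.lists(categories, min_size=1, max_size=150)
cells = st.integers(min_value=0, max_value=40)


class TestCrosstab:
    def test_identical_lists_put_all_mass_on_the_diagonal(self):
        tab = crosstab([0, 1, 2, 3, 3], [0, 1, 2, 3, 3])
        assert np.trace(tab.counts) == 5 and tab.n == 5

    def test_margins_reproduce_per_scale_counts(self, rng):
        sf = np.repeat([0, 1, 2, 3], [13, 46, 20, 38])
        lf = np.repeat([0, 1, 2, 3], [30, 21, 31, 35])
        rng.shuffle(lf)
        tab = crosstab(sf, lf)
        assert tab.n == 117
        assert tab.sf_margin.tolist() == [13, 46, 20, 38]
        assert sorted(tab.lf_margin.tolist()) == sorted([30, 21, 31, 35])

    @settings(max_examples=100, derandomize=True)
    @given(cat_lists)
    def test_cell_sum_is_always_n(self, sf):
        lf = list(reversed(sf))
        assert crosstab(sf, lf).n == len(sf)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            crosstab([], [])
        with pytest.raises(ValidationError):
            crosstab([0, 1], [0])
        with pytest.raises(ValidationError):
            crosstab([0, 4], [0, 1])


class TestConcordanceProportion:
    def test_diagonal_table_meets_endpoint(self):
        rep = concordance_proportion(crosstab([0, 1, 2, 3], [0, 1, 2, 3]))
        assert rep.exact_agreement == 1.0 and rep.meets_primary_endpoint

    def test_anti_diagonal_table_fails_endpoint(self):
        rep = concordance_proportion(crosstab([0, 1, 2, 3], [3, 2, 1, 0]))
        assert rep.exact_agreement == 0.0 and not rep.meets_primary_endpoint

    @settings(max_examples=100, derandomize=True)
    @given(cat_lists, st.randoms(use_true_random=False))
    def test_trace_over_n_equals_per_patient_match_count(self, sf, rnd):
        lf = [rnd.randint(0, 3) for _ in sf]
        rep = concordance_proportion(crosstab(sf, lf))
        brute = sum(a == b for a, b in zip(sf, lf)) / len(sf)
        assert rep.exact_agreement == pytest.approx(brute)

    def test_extreme_agreement_restricts_to_good_or_poor(self):
        # good/good, poor/poor, poor/average, average/borderline
        rep = concordance_proportion(crosstab([0, 3, 3, 1], [0, 3, 1, 2]))
        assert rep.n_extreme == 3
        assert rep.extreme_agreement == pytest.approx(2 / 3)


class TestPearsonChi2:
    def test_study_readmission_table(self):
        res = pearson_chi2_2x2(ContingencyTable2x2(5, 8, 31, 7))
        assert res.statistic == pytest.approx(8.674, abs=5e-4)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0032, abs=2e-4)
        assert res.p_value < 0.01

    def test_independent_table_scores_zero(self):
        res = pearson_chi2_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0.0 and res.p_value == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(cells, cells, cells, cells)
    def test_matches_expected_count_oracle(self, a, b, c, d):
        """n(ad-bc)^2/(margins) equals the textbook sum of (O-E)^2/E."""
        tab = ContingencyTable2x2(a, b, c, d)
        arr = tab.as_array().astype(float)
        n = arr.sum()
        rows, cols = arr.sum(1), arr.sum(0)
        if rows.min() == 0 or cols.min() == 0:
            with pytest.raises(ValidationError, match="exact"):
                pearson_chi2_2x2(tab)
            return
        expected = np.outer(rows, cols) / n
        oracle = float(((arr - expected) ** 2 / expected).sum())
        res = pearson_chi2_2x2(tab)
        assert res.statistic == pytest.approx(oracle, abs=1e-9)
        # independent route: scipy's uncorrected chi-square
        sp = stats.chi2_contingency(arr, correction=False)
        assert res.statistic == pytest.approx(sp.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    def test_invariant_under_row_and_column_swaps(self):
        base = pearson_chi2_2x2(ContingencyTable2x2(5, 8, 31, 7)).statistic
        assert pearson_chi2_2x2(ContingencyTable2x2(31, 7, 5, 8)).statistic == pytest.approx(base)
        assert pearson_chi2_2x2(ContingencyTable2x2(8, 5, 7, 31)).statistic == pytest.approx(base)

    def test_yates_correction_shrinks_the_statistic(self):
        tab = ContingencyTable2x2(5, 8, 31, 7)
        corrected = pearson_chi2_2x2(tab, correction=True)
        assert corrected.statistic < pearson_chi2_2x2(tab).statistic
        sp = stats.chi2_contingency(tab.as_array(), correction=True)
        assert corrected.statistic == pytest.approx(sp.statistic, abs=1e-9)


class TestExactTest:
    def test_two_by_two_identity_table(self):
        assert exact_test_2x2(ContingencyTable2x2(1, 0, 0, 1)) == pytest.approx(1.0)

    def test_five_by_five_diagonal(self):
        assert exact_test_2x2(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(1 / 126)

    @settings(max_examples=150, derandomize=True)
    @given(cells, cells, cells, cells)
    def test_matches_scipy_fisher_and_stays_in_unit_interval(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = exact_test_2x2(ContingencyTable2x2(a, b, c, d))
        assert 0 < p <= 1
        _, sp = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(sp, rel=1e-7, abs=1e-12)

    def test_study_table_decisions(self):
        # the exact test is conservative on this table: it lands just above
        # 0.01 while the chi-square sits well below; both reject at 0.05
        tab = ContingencyTable2x2(5, 8, 31, 7)
        p_exact = exact_test_2x2(tab)
        assert p_exact == pytest.approx(0.0106, abs=5e-4)
        assert (p_exact < 0.05) and (pearson_chi2_2x2(tab).p_value < 0.05)


class TestCategoryDistributionStats:
    def test_study_sf_counts(self):
        st_ = category_distribution_stats([13, 46, 20, 38])
        assert round(st_.mean, 2) == 1.71
        assert round(st_.sd, 2) == 1.04
        assert st_.range == (0, 3) and st_.n == 117

    def test_degenerate_single_category(self):
        st_ = category_distribution_stats([0, 0, 9, 0])
        assert st_.mean == 2.0 and st_.sd == 0.0 and st_.range == (2, 2)

    def test_two_patient_closed_form(self):
        st_ = category_distribution_stats([1, 1])
        assert st_.mean == pytest.approx(0.5)
        assert st_.sd == pytest.approx(np.sqrt(0.5))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=8))
    def test_matches_expanded_list_oracle(self, counts):
        if sum(counts) == 0:
            with pytest.raises(ValidationError):
                category_distribution_stats(counts)
            return
        expanded = np.repeat(np.arange(len(counts)), counts)
        st_ = category_distribution_stats(counts)
        assert st_.mean == pytest.approx(expanded.mean())
        if expanded.size > 1:
            assert st_.sd == pytest.approx(expanded.std(ddof=1))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValidationError):
            category_distribution_stats([0, 0, 0, 0])
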