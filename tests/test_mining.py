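from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_metrics, brute_rules, enumerate_itemsets
from conftest import TOY_ROWS, make_matrix, random_matrix
from survrule.cohort import Item
from survrule.mining import (
    ContingencyTable,
    Itemset,
    MiningError,
    compute_metrics,
    contingency,
    generate_rules,
    mine_frequent_itemsets,
)

# strategy for non-degenerate 2x2 tables with |A| >= 1
tables = st.tuples(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
).filter(lambda t: t[0] + t[1] >= 1 and sum(t) >= 1)


def item(j: int) -> Item:
    return Item("attr", f"i{j}")


class TestMineFrequentItemsets:
    @pytest.mark.parametrize("min_support", [0.0, 0.1, 0.25, 0.5])
    @pytest.mark.parametrize("max_len", [1, 2, 4])
    def test_matches_exhaustive_enumeration(self, toy_matrix, min_support, max_len):
        rows = [set(r) for r in TOY_ROWS]
        expected = enumerate_itemsets(rows, 4, min_support, max_len)
        mined = mine_frequent_itemsets(toy_matrix, min_support, max_len)
        got = {
            frozenset(int(i.category[1:]) for i in s.items): s.support_count
            for s in mined
        }
        assert got == expected

    def test_min_support_zero_singletons(self, toy_matrix):
        mined = mine_frequent_itemsets(toy_matrix, 0.0, 1)
        assert len(mined) == 4
        assert all(len(s.items) == 1 for s in mined)

    def test_threshold_monotonicity(self, toy_matrix):
        at_30 = {s.items for s in mine_frequent_itemsets(toy_matrix, 0.3, 3)}
        at_20 = {s.items for s in mine_frequent_itemsets(toy_matrix, 0.2, 3)}
        assert at_30 <= at_20

    def test_apriori_downward_closure(self, toy_matrix):
        mined = mine_frequent_itemsets(toy_matrix, 0.2, 3)
        found = {s.items for s in mined}
        for itemset in mined:
            for member in itemset.items:
                subset = itemset.items - {member}
                if subset:
                    assert subset in found

    def test_empty_matrix_errors(self):
        matrix = make_matrix([], 3)
        with pytest.raises(MiningError, match="empty"):
            mine_frequent_itemsets(matrix, 0.1, 1)

    def test_bad_parameters(self, toy_matrix):
        with pytest.raises(MiningError):
            mine_frequent_itemsets(toy_matrix, -0.1, 1)
        with pytest.raises(MiningError):
            mine_frequent_itemsets(toy_matrix, 0.1, 0)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            matrix = random_matrix(rng, n_rows=30, n_items=6)
            rows = [set(np.flatnonzero(r)) for r in matrix.incidence]
            expected = enumerate_itemsets(rows, 6, 0.15, 3)
            mined = mine_frequent_itemsets(matrix, 0.15, 3)
            got = {
                frozenset(int(i.category[1:]) for i in s.items): s.support_count
                for s in mined
            }
            assert got == expected


class TestContingency:
    def test_hand_count(self, toy_matrix):
        table = contingency(toy_matrix, [item(0)], item(1))
        assert (table.n11, table.n10, table.n01, table.n00) == (3, 1, 2, 4)
        assert table.a_count == 4 and table.b_count == 5 and table.total == 10

    def test_disjoint_items(self, toy_matrix):
        # items 0 and 2 co-occur once in TOY_ROWS; build a disjoint pair
        matrix = make_matrix([[0], [1], [0], [1]], 2)
        table = contingency(matrix, [item(0)], item(1))
        assert table.n11 == 0

    def test_self_pair(self, toy_matrix):
        table = contingency(toy_matrix, [item(2)], item(2))
        assert table.n10 == 0 and table.n01 == 0

    def test_unknown_item_errors(self, toy_matrix):
        with pytest.raises(MiningError, match="not in catalog"):
            contingency(toy_matrix, [Item("attr", "i9")], item(0))

    def test_counts_sum_to_n(self, toy_matrix):
        table = contingency(toy_matrix, [item(0), item(1)], item(2))
        assert table.total == toy_matrix.n_patients


class TestComputeMetrics:
    def test_derived_reference_table(self):
        m = compute_metrics(ContingencyTable(3, 1, 2, 4))
        assert m.support == pytest.approx(0.300)
        assert m.confidence == pytest.approx(0.750)
        assert m.lift == pytest.approx(1.500)
        assert m.cosine == pytest.approx(0.6708, abs=1e-4)
        assert m.correlation == pytest.approx(0.4082, abs=1e-4)
        assert m.chi_square == pytest.approx(1.6667, abs=1e-4)
        assert m.odds_ratio == pytest.approx(6.0)

    def test_perfect_association(self):
        m = compute_metrics(ContingencyTable(4, 0, 0, 6))
        assert m.confidence == 1.0
        assert m.cosine == 1.0
        assert m.correlation == pytest.approx(1.0)
        assert m.chi_square == pytest.approx(10.0)  # equals N

    def test_exact_independence(self):
        # |A| = 4, |B| = 5, N = 10 -> n11 = 2 is exact independence
        m = compute_metrics(ContingencyTable(2, 2, 3, 3))
        assert m.lift == pytest.approx(1.0)
        assert m.correlation == pytest.approx(0.0)
        assert m.chi_square == pytest.approx(0.0)

    def test_empty_antecedent_errors(self):
        with pytest.raises(MiningError, match="antecedent"):
            compute_metrics(ContingencyTable(0, 0, 5, 5))

    def test_degenerate_marginal_flags_nan_correlation(self):
        m = compute_metrics(ContingencyTable(5, 0, 5, 0))  # |B| = N
        assert math.isnan(m.correlation)
        assert m.chi_square == 0.0

    def test_zero_cooccurrence_lift_zero(self):
        m = compute_metrics(ContingencyTable(0, 4, 5, 1))
        assert m.lift == 0.0
        assert m.cosine == 0.0
        assert m.support == 0.0

    def test_haldane_anscombe_on_zero_cell(self):
        m = compute_metrics(ContingencyTable(4, 0, 1, 5))
        expected = (4.5 * 5.5) / (0.5 * 1.5)
        assert m.odds_ratio == pytest.approx(expected)
        assert 0 < m.or_ci_low < m.odds_ratio < m.or_ci_high

    def test_matches_scipy_chi2(self):
        from scipy import stats

        observed = [[3, 1], [2, 4]]
        expected = stats.chi2_contingency(observed, correction=False)[0]
        m = compute_metrics(ContingencyTable(3, 1, 2, 4))
        assert m.chi_square == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_on_toy(self, toy_matrix):
        table = contingency(toy_matrix, [item(0)], item(1))
        m = compute_metrics(table)
        rows = [set(r) for r in TOY_ROWS]
        oracle = brute_metrics(rows, {0}, 1)
        for key, value in oracle.items():
            assert getattr(m, key) == pytest.approx(value, rel=1e-12)


class TestMeasureProperties:
    @given(tables)
    def test_chi_square_is_n_phi_squared(self, t):
        m = compute_metrics(ContingencyTable(*t))
        if not math.isnan(m.correlation):
            assert m.chi_square == pytest.approx(
                sum(t) * m.correlation**2, rel=1e-9, abs=1e-12
            )

    @given(tables.filter(lambda t: t[0] + t[2] >= 1))
    def test_cosine_is_geometric_mean_of_confidences(self, t):
        table = ContingencyTable(*t)
        forward = compute_metrics(table)
        backward = compute_metrics(table.swapped())
        assert forward.cosine == pytest.approx(
            math.sqrt(forward.confidence * backward.confidence), rel=1e-9, abs=1e-12
        )

    @given(tables.filter(lambda t: t[0] + t[2] >= 1))
    def test_support_and_lift_symmetric(self, t):
        table = ContingencyTable(*t)
        forward = compute_metrics(table)
        backward = compute_metrics(table.swapped())
        assert forward.support == backward.support
        assert forward.lift == pytest.approx(backward.lift, rel=1e-12)

    @given(tables)
    def test_bounds(self, t):
        table = ContingencyTable(*t)
        m = compute_metrics(table)
        n = table.total
        assert 0 <= m.support <= m.confidence <= 1
        assert m.support <= min(table.a_count, table.b_count) / n
        assert 0 <= m.cosine <= 1 + 1e-12
        if not math.isnan(m.correlation):
            assert -1 - 1e-12 <= m.correlation <= 1 + 1e-12
        assert m.chi_square >= 0
        assert m.odds_ratio >= 0

    @given(tables.filter(lambda t: t[0] + t[2] >= 1 and t[0] > 0))
    def test_lift_equals_confidence_over_prior(self, t):
        table = ContingencyTable(*t)
        m = compute_metrics(table)
        prior = table.b_count / table.total
        assert m.lift == pytest.approx(m.confidence / prior, rel=1e-12)


class TestGenerateRules:
    def outcome_pair(self):
        return [item(2), item(3)]

    def test_antecedents_exclude_outcomes(self, toy_matrix):
        itemsets = mine_frequent_itemsets(toy_matrix, 0.0, 2)
        rules = generate_rules(itemsets, toy_matrix, self.outcome_pair(), 0.0)
        for rule in rules:
            assert not rule.antecedent.items & set(self.outcome_pair())

    def test_rule_count_matches_exhaustive(self, toy_matrix):
        itemsets = mine_frequent_itemsets(toy_matrix, 0.1, 2)
        rules = generate_rules(itemsets, toy_matrix, self.outcome_pair(), 0.0)
        rows = [set(r) for r in TOY_ROWS]
        oracle = brute_rules(rows, 4, [2, 3], 0.1, 0.0, 2)
        assert len(rules) == len(oracle)
        nonoutcome = [
            s for s in itemsets if not s.items & set(self.outcome_pair())
            if s.support_count > 0
        ]
        assert len(rules) == 2 * len(nonoutcome)

    def test_full_scores_match_exhaustive(self, toy_matrix):
        itemsets = mine_frequent_itemsets(toy_matrix, 0.1, 2)
        rules = generate_rules(itemsets, toy_matrix, self.outcome_pair(), 0.0)
        rows = [set(r) for r in TOY_ROWS]
        oracle = {
            (frozenset(a), b): metrics
            for a, b, metrics in brute_rules(rows, 4, [2, 3], 0.1, 0.0, 2)
        }
        for rule in rules:
            key = (
                frozenset(int(i.category[1:]) for i in rule.antecedent.items),
                int(rule.consequent.category[1:]),
            )
            expected = oracle[key]
            for name, value in expected.items():
                got = getattr(rule.metrics, name)
                if math.isnan(value):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(value, rel=1e-12)

    def test_min_confidence_excludes(self, toy_matrix):
        itemsets = mine_frequent_itemsets(toy_matrix, 0.1, 1)
        rules = generate_rules(itemsets, toy_matrix, [item(1)], 1.0)
        # no antecedent predicts item 1 perfectly in TOY_ROWS
        assert rules == []

    def test_empty_consequents_error(self, toy_matrix):
        with pytest.raises(MiningError):
            generate_rules([], toy_matrix, [], 0.5)


class TestItemsetType:
    def test_negative_support_rejected(self):
        with pytest.raises(MiningError):
            Itemset(frozenset([item(0)]), -1)

    def test_canonical_sorted(self):
        s = Itemset(frozenset([item(3), item(1)]), 2)
        assert s.canonical == "attr: i1 & attr: i3"
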