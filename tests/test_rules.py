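"""Rule generation, 2x2 independence statistics and classification."""

import math
import random

import pytest

from cooccur import (
    AssociationRule,
    ContingencyCounts,
    EmptyInputError,
    FrequentItemset,
    RuleThresholds,
    chi_square_statistic,
    classify_rule,
    contingency_table,
    directional_p_value,
    find_frequent_itemsets,
    generate_candidate_rules,
    score_and_classify,
    summarize_rules,
)

from _oracles import hypergeom_upper_tail


def fs(*items):
    return frozenset(items)


def _frequent(support_map):
    return [FrequentItemset(items, sup, 0) for items, sup in support_map.items()]


class TestGenerateCandidateRules:
    SUPPORTS = {fs("A"): 0.8, fs("B"): 0.6, fs("A", "B"): 0.4}

    def test_confidence_is_joint_over_antecedent(self):
        rules = generate_candidate_rules(
            _frequent(self.SUPPORTS), RuleThresholds(min_confidence=0.3)
        )
        by_ante = {tuple(sorted(r.antecedent)): r for r in rules}
        assert by_ante[("A",)].confidence == pytest.approx(0.5)
        assert by_ante[("B",)].confidence == pytest.approx(0.4 / 0.6)

    def test_confidence_gate_suppresses_low_direction(self):
        rules = generate_candidate_rules(
            _frequent(self.SUPPORTS), RuleThresholds(min_confidence=0.6)
        )
        assert [tuple(sorted(r.antecedent)) for r in rules] == [("B",)]

    def test_singleton_itemsets_yield_no_rules(self):
        assert generate_candidate_rules(_frequent({fs("A"): 0.8})) == []

    def test_lift_symmetric_across_directions(self):
        rules = generate_candidate_rules(_frequent(self.SUPPORTS))
        lifts = {r.lift for r in rules}
        assert len(lifts) == 1
        assert lifts.pop() == pytest.approx(0.4 / (0.8 * 0.6))

    def test_three_item_sets_split_every_way(self):
        supports = {
            fs("A"): 0.6, fs("B"): 0.6, fs("C"): 0.6,
            fs("A", "B"): 0.5, fs("A", "C"): 0.5, fs("B", "C"): 0.5,
            fs("A", "B", "C"): 0.4,
        }
        rules = generate_candidate_rules(
            _frequent(supports), RuleThresholds(min_confidence=0.0)
        )
        three = [r for r in rules if len(r.items) == 3]
        assert len(three) == 6  # 2^3 - 2 proper splits

    def test_metric_identity_confidence_times_antecedent_support(self):
        corpus = [fs("A", "B", "C"), fs("A", "B"), fs("A", "C"), fs("B", "C"), fs("A")]
        frequent = find_frequent_itemsets(corpus, 0.2)
        for r in generate_candidate_rules(frequent, RuleThresholds(min_confidence=0.0)):
            sup_a = next(f.support for f in frequent if f.items == r.antecedent)
            assert r.confidence * sup_a == pytest.approx(r.support, abs=1e-12)


class TestContingencyTable:
    def test_counts_partition_transactions(self):
        corpus = [fs("A", "B")] * 4 + [fs("A")] * 4 + [fs("B")] + [fs("C")]
        rule = AssociationRule(fs("A"), fs("B"), 0.4, 0.5, 1.0)
        counts = contingency_table(rule, corpus)
        assert (counts.N, counts.n11, counts.n10, counts.n01, counts.n00) == (10, 4, 4, 1, 1)

    def test_single_joint_transaction(self):
        rule = AssociationRule(fs("A"), fs("B"), 1.0, 1.0, 1.0)
        counts = contingency_table(rule, [fs("A", "B")])
        assert (counts.N, counts.n11, counts.n10, counts.n01, counts.n00) == (1, 1, 0, 0, 0)

    def test_neither_side_present(self):
        rule = AssociationRule(fs("A"), fs("B"), 0.0, 0.0, 0.0)
        counts = contingency_table(rule, [fs("C"), fs("C")])
        assert (counts.N, counts.n11, counts.n00) == (2, 0, 2)

    def test_empty_transactions_raise(self):
        rule = AssociationRule(fs("A"), fs("B"), 0.0, 0.0, 0.0)
        with pytest.raises(EmptyInputError):
            contingency_table(rule, [])


class TestChiSquare:
    def test_hand_computed_value(self):
        chi2, p = chi_square_statistic(ContingencyCounts(80, 30, 10, 10, 30))
        assert chi2 == pytest.approx(20.0)
        assert 0 < p < 1e-4

    def test_observed_equals_expected(self):
        assert chi_square_statistic(ContingencyCounts(40, 10, 10, 10, 10)) == (0.0, 1.0)

    def test_degenerate_margin_convention(self):
        # consequent present in every transaction: zero column margin
        assert chi_square_statistic(ContingencyCounts(10, 4, 0, 6, 0)) == (0.0, 1.0)

    def test_swap_invariance(self):
        a = chi_square_statistic(ContingencyCounts(50, 20, 5, 10, 15))
        b = chi_square_statistic(ContingencyCounts(50, 20, 10, 5, 15))  # sides swapped
        assert a == pytest.approx(b)


class TestDirectionalPValue:
    def test_hand_computed_tail(self):
        # N=4, both margins 2, full overlap: C(2,2)C(2,0)/C(4,2) = 1/6
        p = directional_p_value(ContingencyCounts(4, 2, 0, 0, 2))
        assert p == pytest.approx(1 / 6)

    def test_zero_overlap_zero_draws(self):
        assert directional_p_value(ContingencyCounts(4, 0, 2, 0, 2)) == pytest.approx(1.0)

    def test_degenerate_margin_gives_one(self):
        # consequent in all N transactions: single-point distribution
        assert directional_p_value(ContingencyCounts(10, 4, 0, 6, 0)) == pytest.approx(1.0)

    def test_swap_invariance(self):
        a = directional_p_value(ContingencyCounts(50, 20, 5, 10, 15))
        b = directional_p_value(ContingencyCounts(50, 20, 10, 5, 15))
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("N", [5, 12, 30])
    def test_matches_enumeration_oracle(self, N):
        rng = random.Random(N)
        for _ in range(60):
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            lo = max(0, K + n - N)
            n11 = rng.randint(lo, min(K, n))
            counts = ContingencyCounts(N, n11, K - n11, n - n11, N - K - n + n11)
            assert directional_p_value(counts) == pytest.approx(
                hypergeom_upper_tail(N, K, n, n11), abs=1e-12
            )


class TestClassifyRule:
    @staticmethod
    def _rule(lift, support=0.5, confidence=0.8):
        return AssociationRule(fs("A"), fs("B"), support, confidence, lift)

    def test_high_lift_low_p_is_positive(self):
        counts = ContingencyCounts(40, 20, 0, 0, 20)  # perfect co-occurrence
        assert classify_rule(self._rule(2.0), counts) == "positive"

    def test_low_lift_high_p_is_negative(self):
        counts = ContingencyCounts(40, 0, 20, 20, 0)  # perfect avoidance
        assert classify_rule(self._rule(0.5), counts) == "negative"

    def test_unit_lift_is_independent(self):
        counts = ContingencyCounts(40, 10, 10, 10, 10)
        assert classify_rule(self._rule(1.0), counts) == "independent"

    def test_failing_gates_is_negligible(self):
        counts = ContingencyCounts(40, 10, 10, 10, 10)
        rule = self._rule(1.0, support=0.05, confidence=0.1)
        assert classify_rule(rule, counts) == "negligible"

    def test_ubiquitous_consequent_never_positive(self):
        # consequent in every transaction: lift may exceed 1 but p = 1
        counts = ContingencyCounts(10, 4, 0, 6, 0)
        rule = self._rule(2.5, support=0.4, confidence=1.0)
        assert classify_rule(rule, counts) != "positive"


class TestScoreAndClassify:
    def test_perfectly_cooccurring_pair_with_background(self):
        corpus = [fs("A", "B")] * 30 + [fs("C", "D")] * 30
        frequent = find_frequent_itemsets(corpus, 0.15)
        rules = score_and_classify(generate_candidate_rules(frequent), corpus)
        assert len(rules) == 4
        assert all(r.label == "positive" for r in rules)
        assert all(r.lift == pytest.approx(2.0) for r in rules)

    def test_support_one_pair_is_never_positive(self):
        # both species in every transaction: degenerate margins
        corpus = [fs("A", "B")] * 50
        frequent = find_frequent_itemsets(corpus, 0.15)
        rules = score_and_classify(generate_candidate_rules(frequent), corpus)
        assert len(rules) == 2
        assert all(r.support == 1.0 and r.p_value == 1.0 for r in rules)
        assert sum(r.label == "positive" for r in rules) == 0

    def test_bonferroni_tightens_alpha(self):
        corpus = [fs("A", "B")] * 4 + [fs("A")] * 3 + [fs("B")] * 3 + [fs("C", "D")] * 4
        frequent = find_frequent_itemsets(corpus, 0.1)
        candidates = generate_candidate_rules(frequent, RuleThresholds(min_support=0.1))
        plain = score_and_classify(candidates, corpus, RuleThresholds(min_support=0.1))
        bonf = score_and_classify(
            candidates, corpus, RuleThresholds(min_support=0.1, bonferroni=True)
        )
        n_pos_plain = sum(r.label == "positive" for r in plain)
        n_pos_bonf = sum(r.label == "positive" for r in bonf)
        assert n_pos_bonf <= n_pos_plain


class TestSummaries:
    def test_tables_for_simple_rule_set(self):
        corpus = [fs("A", "B"), fs("A")]
        rules = [
            AssociationRule(fs("A"), fs("B"), 0.5, 0.5, 1.0, 0.0, 0.5, "positive"),
            AssociationRule(fs("A", "B"), fs("C"), 0.2, 0.4, 1.1, 0.0, 0.5, "independent"),
        ]
        tables = summarize_rules(rules, corpus)
        appearances = dict(
            zip(tables["appearances"]["species"], tables["appearances"]["positive_rule_appearances"])
        )
        assert appearances == {"A": 1, "B": 1}
        roles = tables["roles"].set_index("species")
        assert roles.loc["A", "antecedent"] == 2
        assert roles.loc["B", "consequent"] == 1
        freq = dict(
            zip(
                tables["transaction_frequency"]["species"],
                tables["transaction_frequency"]["transaction_fraction"],
            )
        )
        assert freq == {"A": 1.0, "B": 0.5}
        sizes = dict(zip(tables["rule_sizes"]["rule_size"], tables["rule_sizes"]["n_rules"]))
        assert sizes == {2: 1, 3: 1}


class TestRuleInvariants:
    def test_sides_must_be_disjoint_and_nonempty(self):
        with pytest.raises(ValueError):
            AssociationRule(fs("A"), fs("A", "B"), 0.5, 0.5, 1.0)
        with pytest.raises(ValueError):
            AssociationRule(fs(), fs("B"), 0.5, 0.5, 1.0)

    def test_contingency_must_sum_to_n(self):
        with pytest.raises(ValueError):
            ContingencyCounts(5, 1, 1, 1, 1)
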