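"""Rule metrics, generation, filtering and rendering."""

import pytest

from surveyrules import (
    AssociationRule,
    Codebook,
    CodebookError,
    RuleThresholds,
    confidence,
    generate_rules,
    lift,
    mine_frequent,
    rule_to_text,
    verify_rule,
)


class TestMetrics:
    def test_confidence_on_contingency_cohort(self, toy_transactions):
        assert confidence({"NegFB"}, {"Creative"}, toy_transactions) == 0.75

    def test_lift_on_contingency_cohort(self, toy_transactions):
        # 0.15 / (0.2 * 0.9)
        assert lift({"NegFB"}, {"Creative"}, toy_transactions) == pytest.approx(
            0.8333, abs=5e-5
        )

    def test_perfect_implication(self):
        tx = [frozenset("xy")] * 3 + [frozenset("z")]
        assert confidence({"x"}, {"y"}, tx) == 1.0

    def test_never_cooccurring(self):
        tx = [frozenset("x"), frozenset("y")]
        assert confidence({"x"}, {"y"}, tx) == 0.0

    def test_confidence_undefined_without_antecedent(self):
        with pytest.raises(ZeroDivisionError):
            confidence({"missing"}, {"y"}, [frozenset("y")])

    def test_lift_symmetry(self, toy_transactions):
        assert lift({"NegFB"}, {"Creative"}, toy_transactions) == lift(
            {"Creative"}, {"NegFB"}, toy_transactions
        )

    def test_lift_one_under_independence(self):
        # x and y occur independently at rate 1/2: joint 1/4
        tx = [frozenset("xy"), frozenset("x"), frozenset("y"), frozenset()]
        assert lift({"x"}, {"y"}, tx) == 1.0

    def test_lift_undefined_on_zero_marginal(self):
        with pytest.raises(ZeroDivisionError):
            lift({"x"}, {"q"}, [frozenset("x")])


class TestGenerateRules:
    def test_lift_filter_drops_negatively_associated_rule(self, toy_transactions):
        frequent = mine_frequent(toy_transactions, minsup=0.10)
        permissive = generate_rules(
            frequent, RuleThresholds(0.10, 0.70, 1e-9), n_transactions=1000
        )
        keys = {r.key for r in permissive}
        assert "NegFB -> Creative" in keys  # s=0.15, c=0.75 passes sup/conf
        strict = generate_rules(
            frequent, RuleThresholds(0.10, 0.70, 1.2), n_transactions=1000
        )
        assert "NegFB -> Creative" not in {r.key for r in strict}

    def test_singletons_yield_no_rules(self):
        tx = [frozenset("a")] * 4
        frequent = mine_frequent(tx, 0.5)
        assert generate_rules(frequent, RuleThresholds(0.5, 0.5, 0.0)) == []

    def test_all_bipartitions_of_perfect_triple(self):
        # {a,b,c} co-occur in 2 of 4 baskets; every marginal is 0.5
        tx = [frozenset("abc"), frozenset("abc"), frozenset("d"), frozenset("e")]
        frequent = mine_frequent(tx, 0.5)
        rules = generate_rules(
            frequent,
            RuleThresholds(0.5, 0.70, 1.0),
            single_consequent=False,
            n_transactions=4,
        )
        triple = [r for r in rules if len(r.antecedent | r.consequent) == 3]
        assert len(triple) == 6  # every bipartition of {a, b, c}
        for rule in triple:
            assert rule.confidence == 1.0
            assert rule.lift == 2.0
        singles = generate_rules(
            frequent, RuleThresholds(0.5, 0.70, 1.0), n_transactions=4
        )
        assert {
            r.key for r in singles if len(r.antecedent | r.consequent) == 3
        } == {"b c -> a", "a c -> b", "a b -> c"}

    def test_emitted_metrics_reverify_by_scan(self, toy_transactions):
        thresholds = RuleThresholds(0.10, 0.70, 1e-9)
        frequent = mine_frequent(toy_transactions, thresholds.minsup)
        rules = generate_rules(frequent, thresholds, n_transactions=1000)
        assert rules
        for rule in rules:
            assert verify_rule(rule, toy_transactions, thresholds)

    def test_confidence_at_least_support(self, toy_transactions):
        frequent = mine_frequent(toy_transactions, 0.05)
        for rule in generate_rules(
            frequent, RuleThresholds(0.05, 0.05, 0.0), n_transactions=1000
        ):
            assert rule.confidence >= rule.support

    def test_threshold_monotonicity(self, toy_transactions):
        base = RuleThresholds(0.05, 0.50, 0.5)
        frequent = mine_frequent(toy_transactions, base.minsup)
        baseline = {
            r.key
            for r in generate_rules(frequent, base, n_transactions=1000)
        }
        for stricter in [
            RuleThresholds(0.2, 0.50, 0.5),
            RuleThresholds(0.05, 0.80, 0.5),
            RuleThresholds(0.05, 0.50, 1.2),
        ]:
            strict_frequent = mine_frequent(toy_transactions, stricter.minsup)
            stricter_keys = {
                r.key
                for r in generate_rules(strict_frequent, stricter, n_transactions=1000)
            }
            assert stricter_keys <= baseline

    def test_sorted_by_lift_then_confidence(self, toy_transactions):
        frequent = mine_frequent(toy_transactions, 0.05)
        rules = generate_rules(
            frequent, RuleThresholds(0.05, 0.05, 0.0), n_transactions=1000
        )
        ordering = [(-r.lift, -r.confidence, r.key) for r in rules]
        assert ordering == sorted(ordering)

    def test_shared_support_within_one_itemset(self, toy_transactions):
        """All bipartition rules of a fixed Z share support; confidences vary."""
        frequent = mine_frequent(toy_transactions, 0.05)
        rules = generate_rules(
            frequent,
            RuleThresholds(0.05, 0.0001, 0.0),
            single_consequent=False,
            n_transactions=1000,
        )
        by_z = {}
        for rule in rules:
            by_z.setdefault(frozenset(rule.antecedent | rule.consequent), set()).add(
                rule.support
            )
        for supports in by_z.values():
            assert len(supports) == 1


class TestRuleInvariants:
    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            AssociationRule(
                antecedent=frozenset("a"),
                consequent=frozenset("a"),
                count=1,
                support=0.5,
                confidence=0.5,
                lift=1.0,
            )

    def test_empty_sides_rejected(self):
        with pytest.raises(ValueError):
            AssociationRule(
                antecedent=frozenset(),
                consequent=frozenset("a"),
                count=1,
                support=0.5,
                confidence=0.5,
                lift=1.0,
            )


class TestRuleToText:
    def _rule(self):
        return AssociationRule(
            antecedent=frozenset({"2-0", "37-2", "41-4"}),
            consequent=frozenset({"38-2"}),
            count=2,
            support=0.2,
            confidence=0.75,
            lift=1.4,
        )

    def test_expands_questions_and_answers(self, small_codebook):
        text = rule_to_text(self._rule(), small_codebook)
        assert "support = 0.20, confidence = 0.75, lift = 1.40" in text
        assert '"2-0": Your gender Answer: Male' in text
        assert '"38-2": COVID-19 is a hopeless disease. Answer: Disagree' in text

    def test_empty_codebook_fails(self):
        with pytest.raises(CodebookError):
            rule_to_text(self._rule(), Codebook([]))

    def test_error_names_unknown_question(self, small_codebook):
        rule = AssociationRule(
            antecedent=frozenset({"37-2"}),
            consequent=frozenset({"99-1"}),
            count=1,
            support=0.2,
            confidence=0.8,
            lift=1.3,
        )
        with pytest.raises(CodebookError, match="99"):
            rule_to_text(rule, small_codebook)
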