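"""Rule metrics, split enumeration, strong filtering and typing."""

import itertools
import math

import pytest

from raremine import (
    MiningConfig,
    classify_rules,
    compute_metrics,
    filter_strong,
    generate_rules,
    mine_frequent,
    support_of,
)
from raremine.rules import AssociationRule, RuleMetrics

from conftest import dataset_from_transactions, random_dataset


def make_rule(supp_xy, supp_x, supp_y, band="frequent", ante=("a",), cons=("y",)):
    return AssociationRule(
        antecedent=frozenset(ante),
        consequent=frozenset(cons),
        metrics=compute_metrics(supp_xy, supp_x, supp_y),
        supp_antecedent=supp_x,
        supp_consequent=supp_y,
        band=band,
    )


class TestComputeMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics(0.2, 0.25, 0.5)
        assert m.confidence == pytest.approx(0.8)
        assert m.lift == pytest.approx(1.6)
        assert m.leverage == pytest.approx(0.075)
        assert m.conviction == pytest.approx(2.5)

    def test_independence_gives_neutral_metrics(self):
        m = compute_metrics(0.3 * 0.4, 0.3, 0.4)
        assert m.lift == pytest.approx(1.0)
        assert m.leverage == pytest.approx(0.0, abs=1e-15)
        assert m.conviction == pytest.approx(1.0)

    def test_confidence_one_reports_infinite_conviction(self):
        m = compute_metrics(0.1, 0.1, 0.5)
        assert m.confidence == 1.0
        assert math.isinf(m.conviction)

    def test_conviction_finite_at_full_consequent_support(self):
        m = compute_metrics(0.4, 0.4, 1.0)
        assert m.conviction == 1.0

    def test_inconsistent_supports_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            compute_metrics(0.6, 0.5, 0.5)
        with pytest.raises(ValueError):
            compute_metrics(0.1, 0.0, 0.5)

    def test_metric_identities_to_1e12(self, rng):
        for _ in range(200):
            supp_x = float(rng.uniform(0.05, 1.0))
            supp_y = float(rng.uniform(0.05, 1.0))
            supp_xy = float(rng.uniform(0.0, min(supp_x, supp_y)))
            m = compute_metrics(supp_xy, supp_x, supp_y)
            assert m.lift == pytest.approx(m.confidence / supp_y, rel=1e-12)
            assert m.leverage == pytest.approx(supp_xy - supp_x * supp_y, rel=1e-12, abs=1e-15)
            assert m.confidence >= supp_xy - 1e-15
            if m.confidence < 1:
                assert (m.conviction > 1) == (m.confidence > supp_y)
            if supp_x > 0 and supp_y > 0 and supp_xy > 0:
                assert math.copysign(1, m.leverage) == math.copysign(1, m.lift - 1) or (
                    abs(m.leverage) < 1e-12
                )


class TestGenerateRules:
    def test_pair_pattern_yields_both_directions(self):
        ds = dataset_from_transactions([{"a", "b"}, {"a", "b"}, {"a"}])
        rules = generate_rules(mine_frequent(ds, 0.5), ds)
        splits = {(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent))) for r in rules}
        assert (("a",), ("b",)) in splits
        assert (("b",), ("a",)) in splits

    def test_triple_pattern_yields_six_candidates(self):
        ds = dataset_from_transactions([{"a", "b", "c"}] * 3)
        rules = generate_rules(mine_frequent(ds, 1.0), ds)
        from_triple = [r for r in rules if len(r.antecedent | r.consequent) == 3]
        assert len(from_triple) == 6

    def test_lift_symmetric_across_directions(self):
        ds = dataset_from_transactions([{"a", "b"}, {"a", "b"}, {"a"}, {"b"}])
        rules = generate_rules(mine_frequent(ds, 0.25), ds)
        by_split = {(r.antecedent, r.consequent): r for r in rules}
        ab = by_split[(frozenset("a"), frozenset("b"))]
        ba = by_split[(frozenset("b"), frozenset("a"))]
        assert ab.metrics.lift == pytest.approx(ba.metrics.lift, rel=1e-12)

    def test_metrics_match_row_scan_oracle(self, rng):
        ds = random_dataset(rng, 100, 8, 0.5)
        patterns = mine_frequent(ds, 0.1)
        rules = generate_rules(patterns, ds)
        assert rules  # non-vacuous
        for rule in rules[:: max(1, len(rules) // 50)]:
            supp_x = support_of(ds, rule.antecedent).support
            supp_y = support_of(ds, rule.consequent).support
            supp_xy = support_of(ds, rule.antecedent | rule.consequent).support
            expected = compute_metrics(supp_xy, supp_x, supp_y)
            assert rule.metrics.support == pytest.approx(expected.support, rel=1e-12)
            assert rule.metrics.confidence == pytest.approx(expected.confidence, rel=1e-12)
            assert rule.metrics.lift == pytest.approx(expected.lift, rel=1e-12)

    def test_class_consequent_only_is_a_subset(self, rng):
        ds = dataset_from_transactions(
            [{"a", "b", "yes"}, {"a", "b", "yes"}, {"a", "no"}, {"b", "no"}]
        )
        full = generate_rules(mine_frequent(ds, 0.25), ds)
        restricted = generate_rules(mine_frequent(ds, 0.25), ds, class_consequent_only=True)
        full_keys = {(r.antecedent, r.consequent) for r in full}
        for r in restricted:
            assert len(r.consequent) == 1 and r.consequent <= {"yes", "no"}
            assert (r.antecedent, r.consequent) in full_keys


class TestFilterStrong:
    def test_boundaries_are_strict(self):
        config = MiningConfig(min_sup=0.01, min_rare=0.001)
        exactly_080 = make_rule(0.2, 0.25, 0.5)  # confidence exactly 0.80
        assert filter_strong([exactly_080], config) == []
        lift_one = make_rule(0.3 * 0.4, 0.3, 0.4)  # lift exactly 1
        assert filter_strong([lift_one], config) == []
        passing = make_rule(0.21, 0.25, 0.5)
        assert filter_strong([passing], config) == [passing]

    def test_band_support_windows(self):
        config = MiningConfig(min_sup=0.1, min_rare=0.01, threshold_mode="fraction")
        frequent_too_low = make_rule(0.05, 0.055, 0.06, band="frequent")
        assert filter_strong([frequent_too_low], config) == []
        rare_ok = make_rule(0.05, 0.055, 0.06, band="rare")
        assert filter_strong([rare_ok], config) == [rare_ok]
        rare_too_high = make_rule(0.2, 0.21, 0.25, band="rare")
        assert filter_strong([rare_too_high], config) == []

    def test_infinite_conviction_passes(self):
        config = MiningConfig(min_sup=0.01, min_rare=0.001, threshold_mode="fraction")
        rule = make_rule(0.05, 0.05, 0.5)
        assert math.isinf(rule.metrics.conviction)
        assert filter_strong([rule], config) == [rule]


class TestClassify:
    def test_four_types_by_band_and_class(self):
        rules = [
            make_rule(0.3, 0.35, 0.5, band="frequent", cons=("no",)),
            make_rule(0.3, 0.35, 0.5, band="frequent", cons=("yes",)),
            make_rule(0.005, 0.0055, 0.5, band="rare", cons=("no",)),
            make_rule(0.005, 0.0055, 0.5, band="rare", cons=("yes",)),
        ]
        buckets = classify_rules(rules)
        assert [len(buckets[t]) for t in ("T1", "T2", "T3", "T4")] == [1, 1, 1, 1]
        assert buckets["T1"][0].rule_type == "T1"
        assert buckets["T4"][0].consequent == frozenset({"yes"})

    def test_non_singleton_class_consequent_is_untyped(self):
        rule = make_rule(0.3, 0.35, 0.5, cons=("yes", "M"), ante=("a",))
        buckets = classify_rules([rule])
        assert buckets["untyped"] == [rule]
        assert all(not buckets[t] for t in ("T1", "T2", "T3", "T4"))

    def test_type_sets_are_disjoint(self):
        rules = [
            make_rule(0.3, 0.35, 0.5, band="frequent", cons=("no",), ante=("a",)),
            make_rule(0.004, 0.0045, 0.5, band="rare", cons=("yes",), ante=("b",)),
        ]
        buckets = classify_rules(rules)
        seen = [
            (r.antecedent, r.consequent)
            for t in ("T1", "T2", "T3", "T4")
            for r in buckets[t]
        ]
        assert len(seen) == len(set(seen)) == 2


def test_published_type_examples_reproduce_from_their_supports(worked_examples):
    """The four published example rules: recomputing the metrics from the
    printed support/confidence pairs reproduces lift, leverage and the
    infinite conviction of the confidence-1 rules."""
    for rtype, ex in worked_examples.type_examples.items():
        supp_x = ex.support / ex.confidence
        supp_y = ex.confidence / ex.lift
        m = compute_metrics(ex.support, supp_x, supp_y)
        assert m.confidence == pytest.approx(ex.confidence, rel=1e-9)
        assert m.lift == pytest.approx(ex.lift, rel=1e-9)
        if ex.confidence == 1.0:
            assert math.isinf(m.conviction)
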