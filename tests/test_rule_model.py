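import json
import math

import pytest

from rulerank import (
    AssociationRule,
    FeatureValueItem,
    PatientInstance,
    RuleSet,
    compute_commonality,
    compute_confidence,
    item_matches,
    read_rules,
    rule_matches,
    write_rules,
)

from conftest import make_item, make_rule


def inst(**features):
    return PatientInstance(instance_id="p1", feature_values=features)


class TestItemMatching:
    def test_equals_item(self):
        item = FeatureValueItem("sex", "equals", "F")
        assert item_matches(item, inst(sex="F"))
        assert not item_matches(item, inst(sex="M"))

    def test_interval_right_closed(self):
        item = FeatureValueItem(
            "x", "interval", interval_low=2, interval_high=3, high_inclusive=True
        )
        assert item_matches(item, inst(x=3))
        assert not item_matches(item, inst(x=3.01))
        assert not item_matches(item, inst(x=2))  # left-open

    def test_unbounded_intervals(self):
        low = FeatureValueItem("x", "interval", interval_high=1.5)
        assert item_matches(low, inst(x=-1e9))
        high = FeatureValueItem("x", "interval", interval_low=1.5, high_inclusive=False)
        assert item_matches(high, inst(x=1e9))

    @pytest.mark.parametrize("missing", [None, float("nan")])
    def test_missing_value_never_matches(self, missing):
        assert not item_matches(FeatureValueItem("x", "equals", "a"), inst(x=missing))
        assert not item_matches(
            FeatureValueItem("x", "interval", interval_high=10.0), inst(x=missing)
        )

    def test_unknown_feature_is_an_error_naming_it(self):
        with pytest.raises(KeyError, match="nope"):
            item_matches(FeatureValueItem("nope", "equals", "a"), inst(x=1))

    def test_item_key_identity_ignores_actionability(self):
        a = FeatureValueItem("f", "equals", "v", actionable=True)
        b = FeatureValueItem("f", "equals", "v", actionable=False)
        assert a.item_key == b.item_key
        assert a == b

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            FeatureValueItem("x", "interval", interval_low=2.0, interval_high=2.0)


class TestRuleMatching:
    def test_conjunction(self):
        rule = make_rule(["a", "b"], 0.5, 0.1, n_matched_positive=1)
        assert rule_matches(rule, inst(a="x", b="x"))
        assert not rule_matches(rule, inst(a="x", b="y"))

    def test_empty_lhs_rejected_at_construction(self):
        with pytest.raises(ValueError):
            AssociationRule(
                lhs=(), outcome_label="1", n_matched=1, n_matched_positive=1, n_positive_total=1
            )

    def test_duplicate_feature_rejected(self):
        with pytest.raises(ValueError, match="duplicate feature"):
            AssociationRule(
                lhs=(make_item("a", "x"), make_item("a", "y")),
                outcome_label="1",
                n_matched=1,
                n_matched_positive=1,
                n_positive_total=1,
            )


class TestCountArithmetic:
    @pytest.mark.parametrize(
        "n_matched,n_pos,expected",
        [(46, 24, 52.17), (51, 39, 76.47), (10, 10, 100.0)],
    )
    def test_confidence_percentages(self, n_matched, n_pos, expected):
        assert compute_confidence(n_matched, n_pos) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "n_pos,n_total,expected",
        [(39, 1184, 3.29), (24, 1184, 2.03), (1184, 1184, 100.0)],
    )
    def test_commonality_percentages(self, n_pos, n_total, expected):
        assert compute_commonality(n_pos, n_total) == pytest.approx(expected, abs=0.005)

    def test_undefined_denominators(self):
        with pytest.raises(ZeroDivisionError):
            compute_confidence(0, 0)
        with pytest.raises(ZeroDivisionError):
            compute_commonality(0, 0)

    def test_stored_fractions_equal_count_ratios_exactly(self):
        rule = AssociationRule(
            lhs=(make_item("f"),),
            outcome_label="1",
            n_matched=46,
            n_matched_positive=24,
            n_positive_total=1184,
        )
        assert rule.confidence == 24 / 46
        assert rule.commonality == 24 / 1184
        assert compute_confidence(rule.n_matched, rule.n_matched_positive) == pytest.approx(
            100 * rule.confidence
        )


class TestSerialization:
    def _ruleset(self):
        rules = [
            make_rule(["a", "b"], 0.8, 0.04, n_matched_positive=4),
            AssociationRule(
                lhs=(
                    FeatureValueItem(
                        "x", "interval", interval_low=2.5, interval_high=6.5
                    ),
                ),
                outcome_label="1",
                n_matched=10,
                n_matched_positive=6,
                n_positive_total=100,
                interventions=("do something",),
            ),
            make_rule(["c"], 0.6, 0.03, n_matched_positive=3, actionable=False),
        ]
        return RuleSet(
            rules=rules,
            provenance={"min_commonality": 0.01, "min_confidence": 0.5, "max_items": 5},
            n_positive_total=100,
        )

    def test_round_trip_is_identity(self, tmp_path):
        rs = self._ruleset()
        p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
        write_rules(rs, p1)
        again = read_rules(p1)
        assert [r.lhs for r in again.rules] == [r.lhs for r in rs.rules]
        assert [
            (r.n_matched, r.n_matched_positive, r.n_positive_total, r.interventions)
            for r in again.rules
        ] == [
            (r.n_matched, r.n_matched_positive, r.n_positive_total, r.interventions)
            for r in rs.rules
        ]
        assert [[p.actionable for p in r.lhs] for r in again.rules] == [
            [p.actionable for p in r.lhs] for r in rs.rules
        ]
        write_rules(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_ruleset_round_trips(self, tmp_path):
        path = tmp_path / "empty.json"
        write_rules(RuleSet(rules=[], provenance={}, n_positive_total=0), path)
        assert read_rules(path).rules == []

    def test_threshold_violation_rejected_on_read(self, tmp_path):
        rs = self._ruleset()
        rs.provenance["min_confidence"] = 0.9  # every stored rule is below this
        path = tmp_path / "bad.json"
        write_rules(rs, path)
        with pytest.raises(ValueError, match="confidence"):
            read_rules(path)

    def test_malformed_record_names_index(self, tmp_path):
        path = tmp_path / "broken.json"
        payload = {
            "provenance": {},
            "n_positive_total": 10,
            "rules": [
                {
                    "lhs": [{"feature": "f", "op": "equals", "value": "v"}],
                    "outcome": "1",
                    "n_matched": 5,
                    # n_matched_positive missing
                    "n_positive_total": 10,
                }
            ],
        }
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="index 0"):
            read_rules(path)
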