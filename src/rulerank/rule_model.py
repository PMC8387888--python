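"""Core domain types for rule-based explanations of clinical risk predictions.

A *feature-value pair item* is a single condition on one feature: either an
exact categorical match (``sex = "F"``) or membership in a half-open numeric
interval (``n_ed_visits in (2, 6.5]``).  A *class association rule* is a
conjunction of such items predicting the poor-outcome class.  Two count-based
quality measures drive everything downstream:

* **confidence** — among instances matching the left-hand side, the fraction
  with the poor outcome (the rule's precision);
* **commonality** — among instances with the poor outcome, the fraction
  matching the left-hand side (class-conditional coverage).

Both are stored as exact count ratios; rounding to two decimals happens only
at display time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

__all__ = [
    "FeatureValueItem",
    "AssociationRule",
    "PatientInstance",
    "RuleSet",
    "item_matches",
    "rule_matches",
    "compute_confidence",
    "compute_commonality",
    "read_rules",
    "write_rules",
    "read_instances",
]


def _fmt(x: float) -> str:
    """Canonical fixed formatting for interval endpoints (item-key stability)."""
    if x == math.inf:
        return "inf"
    if x == -math.inf:
        return "-inf"
    if x == int(x):
        return str(int(x))
    return f"{x:.6g}"


@dataclass(frozen=True)
class FeatureValueItem:
    """One condition ``(feature, value-or-interval)``; the atom of a rule LHS.

    ``actionable`` marks whether at least one intervention is linked to the
    item in the catalog; it is deliberately excluded from identity so that the
    same condition with and without catalog entries is still "the same item".
    """

    feature_name: str
    condition_kind: str  # "equals" | "interval"
    category_value: str | None = None
    interval_low: float = -math.inf
    interval_high: float = math.inf
    low_inclusive: bool = False
    high_inclusive: bool = True
    actionable: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.condition_kind not in ("equals", "interval"):
            raise ValueError(f"unknown condition_kind {self.condition_kind!r}")
        if self.condition_kind == "equals":
            if self.category_value is None:
                raise ValueError(f"equals-item on {self.feature_name!r} needs a value")
        else:
            lo, hi = self.interval_low, self.interval_high
            if math.isfinite(lo) and math.isfinite(hi) and not lo < hi:
                raise ValueError(
                    f"interval item on {self.feature_name!r}: low {lo} must be < high {hi}"
                )

    @property
    def item_key(self) -> str:
        """Canonical string identity; a pure function of the condition."""
        if self.condition_kind == "equals":
            return f"{self.feature_name}={self.category_value}"
        lb = "[" if self.low_inclusive else "("
        rb = "]" if self.high_inclusive else ")"
        return f"{self.feature_name} in {lb}{_fmt(self.interval_low)}, {_fmt(self.interval_high)}{rb}"

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.item_key

    def with_actionable(self, actionable: bool) -> "FeatureValueItem":
        return replace(self, actionable=actionable)


@dataclass(frozen=True)
class AssociationRule:
    """A class association rule ``p_1 AND ... AND p_m -> outcome``.

    Confidence and commonality are derived properties of the stored counts, so
    they can never drift from the count arithmetic.
    """

    lhs: tuple[FeatureValueItem, ...]
    outcome_label: str
    n_matched: int
    n_matched_positive: int
    n_positive_total: int
    interventions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.lhs) < 1:
            raise ValueError("a rule needs at least one LHS item")
        features = [p.feature_name for p in self.lhs]
        if len(set(features)) != len(features):
            raise ValueError(f"duplicate feature on rule LHS: {sorted(features)}")
        if not 0 < self.n_matched:
            raise ValueError("n_matched must be positive")
        if not 0 <= self.n_matched_positive <= self.n_matched:
            raise ValueError("n_matched_positive must lie in [0, n_matched]")
        if self.n_matched_positive > self.n_positive_total:
            raise ValueError("n_matched_positive cannot exceed n_positive_total")
        object.__setattr__(self, "lhs", tuple(self.lhs))
        object.__setattr__(self, "interventions", tuple(self.interventions))

    @property
    def n_items(self) -> int:
        return len(self.lhs)

    @property
    def confidence(self) -> float:
        """Fraction of LHS-matching instances with the poor outcome."""
        return self.n_matched_positive / self.n_matched

    @property
    def commonality(self) -> float:
        """Fraction of poor-outcome instances matching the LHS."""
        return self.n_matched_positive / self.n_positive_total

    @property
    def actionable(self) -> bool:
        return any(p.actionable for p in self.lhs)

    @property
    def item_keys(self) -> frozenset[str]:
        return frozenset(p.item_key for p in self.lhs)

    def describe(self) -> str:  # pragma: no cover - display helper
        lhs = " AND ".join(str(p) for p in self.lhs)
        return (
            f"{lhs} -> {self.outcome_label} "
            f"(confidence {100 * self.confidence:.2f}%, commonality {100 * self.commonality:.2f}%)"
        )


@dataclass
class PatientInstance:
    """One patient-period row: feature values plus outcome/prediction fields.

    Missing values are represented as ``None`` (NaN is normalized on load).
    """

    instance_id: str
    feature_values: dict[str, Any]
    outcome: int | None = None
    predicted_positive: bool | None = None
    risk_score: float | None = None


@dataclass
class RuleSet:
    """A mined collection of rules plus the thresholds they were mined under."""

    rules: list[AssociationRule]
    provenance: dict[str, Any] = field(default_factory=dict)
    n_positive_total: int = 0

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def validate(self) -> None:
        """Check every rule against the stored mining thresholds."""
        min_comm = self.provenance.get("min_commonality")
        min_conf = self.provenance.get("min_confidence")
        max_items = self.provenance.get("max_items")
        for i, r in enumerate(self.rules):
            if min_comm is not None and r.commonality < min_comm - 1e-12:
                raise ValueError(
                    f"rule {i}: commonality {r.commonality:.6f} below threshold {min_comm}"
                )
            if min_conf is not None and r.confidence < min_conf - 1e-12:
                raise ValueError(
                    f"rule {i}: confidence {r.confidence:.6f} below threshold {min_conf}"
                )
            if max_items is not None and r.n_items > max_items:
                raise ValueError(f"rule {i}: {r.n_items} LHS items exceed max {max_items}")


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def item_matches(item: FeatureValueItem, instance: PatientInstance) -> bool:
    """True iff the instance's value for the item's feature satisfies the condition.

    A missing value never satisfies a condition (conservative: rules are only
    matched on observed data).  An unknown feature is an error, not a
    non-match, to surface schema mismatches early.
    """
    if item.feature_name not in instance.feature_values:
        raise KeyError(
            f"instance {instance.instance_id!r} has no feature {item.feature_name!r}"
        )
    value = instance.feature_values[item.feature_name]
    if _is_missing(value):
        return False
    if item.condition_kind == "equals":
        return str(value) == str(item.category_value)
    x = float(value)
    above_low = x >= item.interval_low if item.low_inclusive else x > item.interval_low
    below_high = x <= item.interval_high if item.high_inclusive else x < item.interval_high
    return above_low and below_high


def rule_matches(rule: AssociationRule, instance: PatientInstance) -> bool:
    """Conjunction of :func:`item_matches` over the rule's LHS."""
    return all(item_matches(p, instance) for p in rule.lhs)


def compute_confidence(n_matched: int, n_matched_positive: int) -> float:
    """Rule precision as a percentage: ``100 * n_matched_positive / n_matched``."""
    if n_matched == 0:
        raise ZeroDivisionError("confidence undefined: no instance matches the LHS")
    if not 0 <= n_matched_positive <= n_matched:
        raise ValueError("n_matched_positive must lie in [0, n_matched]")
    return 100.0 * n_matched_positive / n_matched


def compute_commonality(n_matched_positive: int, n_positive_total: int) -> float:
    """Class-conditional coverage as a percentage: ``100 * n_matched_positive / n_positive_total``."""
    if n_positive_total == 0:
        raise ZeroDivisionError("commonality undefined: no positive instances")
    return 100.0 * n_matched_positive / n_positive_total


# ---------------------------------------------------------------------------
# (De)serialization


def _item_to_record(item: FeatureValueItem) -> dict[str, Any]:
    if item.condition_kind == "equals":
        return {
            "feature": item.feature_name,
            "op": "equals",
            "value": item.category_value,
            "actionable": item.actionable,
        }
    return {
        "feature": item.feature_name,
        "op": "interval",
        "low": None if item.interval_low == -math.inf else item.interval_low,
        "high": None if item.interval_high == math.inf else item.interval_high,
        "low_inclusive": item.low_inclusive,
        "high_inclusive": item.high_inclusive,
        "actionable": item.actionable,
    }


def _item_from_record(rec: Mapping[str, Any], where: str) -> FeatureValueItem:
    try:
        op = rec["op"]
        if op == "equals":
            return FeatureValueItem(
                feature_name=rec["feature"],
                condition_kind="equals",
                category_value=rec["value"],
                actionable=bool(rec.get("actionable", False)),
            )
        if op == "interval":
            low = rec.get("low")
            high = rec.get("high")
            return FeatureValueItem(
                feature_name=rec["feature"],
                condition_kind="interval",
                interval_low=-math.inf if low is None else float(low),
                interval_high=math.inf if high is None else float(high),
                low_inclusive=bool(rec.get("low_inclusive", False)),
                high_inclusive=bool(rec.get("high_inclusive", True)),
                actionable=bool(rec.get("actionable", False)),
            )
        raise ValueError(f"unknown op {op!r}")
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed item record at {where}: {exc}") from exc


def write_rules(ruleset: RuleSet, path) -> None:
    """Serialize a RuleSet to JSON (counts exactly; fractions are re-derived)."""
    payload = {
        "provenance": ruleset.provenance,
        "n_positive_total": ruleset.n_positive_total,
        "rules": [
            {
                "lhs": [_item_to_record(p) for p in r.lhs],
                "outcome": r.outcome_label,
                "n_matched": r.n_matched,
                "n_matched_positive": r.n_matched_positive,
                "n_positive_total": r.n_positive_total,
                "interventions": list(r.interventions),
            }
            for r in ruleset.rules
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_rules(path) -> RuleSet:
    """Load a RuleSet from JSON, validating records and mining thresholds."""
    with open(path) as fh:
        payload = json.load(fh)
    rules = []
    for i, rec in enumerate(payload.get("rules", [])):
        try:
            lhs = tuple(
                _item_from_record(item, f"rule {i}, item {j}")
                for j, item in enumerate(rec["lhs"])
            )
            rule = AssociationRule(
                lhs=lhs,
                outcome_label=rec["outcome"],
                n_matched=int(rec["n_matched"]),
                n_matched_positive=int(rec["n_matched_positive"]),
                n_positive_total=int(rec["n_positive_total"]),
                interventions=tuple(rec.get("interventions", ())),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed rule record at index {i}: {exc}") from exc
        rules.append(rule)
    ruleset = RuleSet(
        rules=rules,
        provenance=dict(payload.get("provenance", {})),
        n_positive_total=int(payload.get("n_positive_total", 0)),
    )
    ruleset.validate()
    return ruleset


def read_instances(
    path,
    outcome_column: str | None = None,
    id_column: str | None = None,
    risk_score_column: str | None = None,
    predicted_column: str | None = None,
) -> list[PatientInstance]:
    """Read patient instances from a CSV with a header row.

    Every non-designated column is treated as a feature; NaN becomes missing.
    """
    import pandas as pd

    frame = pd.read_csv(path)
    return instances_from_frame(
        frame, outcome_column, id_column, risk_score_column, predicted_column
    )


def instances_from_frame(
    frame,
    outcome_column: str | None = None,
    id_column: str | None = None,
    risk_score_column: str | None = None,
    predicted_column: str | None = None,
) -> list[PatientInstance]:
    import pandas as pd

    special = {c for c in (outcome_column, id_column, risk_score_column, predicted_column) if c}
    feature_cols = [c for c in frame.columns if c not in special]
    instances = []
    for idx, row in frame.iterrows():
        feats = {c: (None if pd.isna(row[c]) else row[c]) for c in feature_cols}
        outcome = None
        if outcome_column is not None and not pd.isna(row[outcome_column]):
            outcome = int(row[outcome_column])
        predicted = None
        if predicted_column is not None and not pd.isna(row[predicted_column]):
            predicted = bool(row[predicted_column])
        risk = None
        if risk_score_column is not None and not pd.isna(row[risk_score_column]):
            risk = float(row[risk_score_column])
        instance_id = str(row[id_column]) if id_column is not None else str(idx)
        instances.append(
            PatientInstance(
                instance_id=instance_id,
                feature_values=feats,
                outcome=outcome,
                predicted_positive=predicted,
                risk_score=risk,
            )
        )
    return instances
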