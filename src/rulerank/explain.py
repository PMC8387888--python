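"""Per-patient explanation retrieval and intervention linking.

For a patient the classifier flags as high risk, every mined rule whose LHS
the patient satisfies is an explanation of the prediction.  A clinician
precompiles zero or more intervention texts per feature-value item; an item
(or rule) with at least one linked intervention is *actionable*.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .rule_model import AssociationRule, PatientInstance, RuleSet, rule_matches

__all__ = [
    "InterventionCatalog",
    "ExplanationSet",
    "find_applicable_rules",
    "attach_interventions",
]


@dataclass
class InterventionCatalog:
    """Mapping from canonical item key to the interventions linked to it."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def interventions_for(self, item_key: str) -> list[str]:
        return self.entries.get(item_key, [])

    def is_actionable(self, item_key: str) -> bool:
        return bool(self.entries.get(item_key))

    def validate_against(self, ruleset: RuleSet) -> None:
        """Reject catalog keys that match no item of the rule set.

        Interval keys must name the mined bins exactly; a stale catalog would
        otherwise silently make every rule nonactionable.
        """
        universe = {p.item_key for r in ruleset.rules for p in r.lhs}
        unknown = sorted(k for k in self.entries if k not in universe)
        if unknown:
            raise ValueError(
                f"catalog keys match no rule item: {unknown[:5]}"
                + ("..." if len(unknown) > 5 else "")
            )

    @classmethod
    def from_csv(cls, path) -> "InterventionCatalog":
        entries: dict[str, list[str]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {
                "item_key",
                "intervention_text",
            } <= set(reader.fieldnames):
                raise ValueError("catalog CSV needs columns item_key, intervention_text")
            for row in reader:
                text = row["intervention_text"].strip()
                entries.setdefault(row["item_key"], [])
                if text:
                    entries[row["item_key"]].append(text)
        return cls(entries=entries)

    @classmethod
    def from_json(cls, path) -> "InterventionCatalog":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(entries={k: list(v) for k, v in raw.items()})

    @classmethod
    def load(cls, path) -> "InterventionCatalog":
        if str(path).endswith(".json"):
            return cls.from_json(path)
        return cls.from_csv(path)


@dataclass
class ExplanationSet:
    """All (unranked) rules applicable to one predicted-positive patient."""

    instance_id: str
    rules: list[AssociationRule]

    @property
    def q(self) -> int:
        """Number of rules found for the patient."""
        return len(self.rules)


def find_applicable_rules(instance: PatientInstance, ruleset: RuleSet) -> ExplanationSet:
    """All rules the patient satisfies; defined only for predicted poor outcomes.

    The set may be empty — explanations cover most, though not all, correctly
    flagged patients.
    """
    if instance.predicted_positive is not True:
        raise ValueError(
            "explanations are defined only for predicted poor outcomes "
            f"(instance {instance.instance_id!r} is not predicted positive)"
        )
    applicable = [r for r in ruleset.rules if rule_matches(r, instance)]
    return ExplanationSet(instance_id=instance.instance_id, rules=applicable)


def attach_interventions(
    rule: AssociationRule, catalog: InterventionCatalog
) -> AssociationRule:
    """Link catalog interventions to a rule and set item actionability flags.

    Interventions are collected in LHS order; a text reachable from two items
    of the same rule is listed once (first occurrence kept).
    """
    new_lhs = tuple(
        p.with_actionable(catalog.is_actionable(p.item_key)) for p in rule.lhs
    )
    seen: dict[str, None] = {}
    for p in rule.lhs:
        for text in catalog.interventions_for(p.item_key):
            seen.setdefault(text)
    return replace(rule, lhs=new_lhs, interventions=tuple(seen))
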