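"""Constrained mining of class association rules for the poor outcome.

Only rules whose right-hand side is the poor-outcome class are mined, under
three constraints: commonality >= a minimum (default 1%), confidence >= a
minimum (default 50%), and at most ``max_items`` LHS items (default 5).  All
thresholds are inclusive.

Commonality is anti-monotone over the positive-class instances, so the search
is a level-wise (Apriori-style) frequent-itemset enumeration restricted to
positive rows with support threshold ``min_commonality``; confidence is then
computed against the full table.  Items on one LHS never share a feature:
under mutually exclusive bins/levels such a conjunction is either redundant
or empty.

A brute-force subset enumerator with the same filters is provided as an
independent test oracle for small tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .discretize import DiscretizationMap
from .rule_model import AssociationRule, FeatureValueItem, RuleSet

__all__ = [
    "MiningConstraints",
    "mine_class_association_rules",
    "enumerate_rules_bruteforce",
    "filter_rules",
]

_EPS = 1e-9
_BRUTEFORCE_ITEM_LIMIT = 20


@dataclass(frozen=True)
class MiningConstraints:
    min_commonality: float = 0.01
    min_confidence: float = 0.50
    max_items: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_commonality <= 1:
            raise ValueError("min_commonality must be in (0, 1]")
        if not 0 < self.min_confidence <= 1:
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")

    def as_dict(self) -> dict:
        return {
            "min_commonality": self.min_commonality,
            "min_confidence": self.min_confidence,
            "max_items": self.max_items,
        }


def _check_discretized(table: pd.DataFrame) -> None:
    for col in table.columns:
        s = table[col]
        if pd.api.types.is_float_dtype(s):
            raise ValueError(
                f"column {col!r} is continuous; discretize it before mining"
            )
        if pd.api.types.is_integer_dtype(s) and s.nunique() > 20:
            raise ValueError(
                f"integer column {col!r} has {s.nunique()} distinct values; "
                "discretize it before mining"
            )


def _build_item_universe(
    table: pd.DataFrame,
    dmap: DiscretizationMap | None,
) -> tuple[list[FeatureValueItem], list[np.ndarray]]:
    """Enumerate (feature, value) items with their full-table match masks.

    Items matching every row carry no information (their conjunction with
    anything is unchanged) and are dropped.  Interval items spanning the
    whole real line (a continuous feature the discretizer left uncut) are
    dropped for the same reason: they only assert that the value is not
    missing.
    """
    n = len(table)
    interval_lookup: dict[tuple[str, str], FeatureValueItem] = {}
    if dmap is not None:
        for feature in dmap.cut_points:
            for it in dmap.items_for(feature):
                interval_lookup[(feature, it.item_key)] = it
    items: list[FeatureValueItem] = []
    masks: list[np.ndarray] = []
    for col in table.columns:
        s = table[col]
        for value in sorted(s.dropna().unique(), key=str):
            mask = (s == value).to_numpy()
            if mask.sum() == n:
                continue
            item = interval_lookup.get((col, str(value)))
            if item is None:
                item = FeatureValueItem(
                    feature_name=col, condition_kind="equals", category_value=str(value)
                )
            elif item.interval_low == -np.inf and item.interval_high == np.inf:
                continue
            items.append(item)
            masks.append(mask)
    return items, masks


def _canonical_sort(rules: list[AssociationRule]) -> list[AssociationRule]:
    """Reproducible file order: confidence desc, commonality desc, lex item keys."""
    return sorted(
        rules,
        key=lambda r: (-r.confidence, -r.commonality, tuple(sorted(r.item_keys))),
    )


def _make_rule(
    item_indices: Sequence[int],
    items: list[FeatureValueItem],
    masks: list[np.ndarray],
    y: np.ndarray,
    outcome_label: str,
) -> AssociationRule:
    full = np.logical_and.reduce([masks[i] for i in item_indices])
    n_matched = int(full.sum())
    n_matched_positive = int((full & (y == 1)).sum())
    lhs = tuple(sorted((items[i] for i in item_indices), key=lambda it: it.item_key))
    return AssociationRule(
        lhs=lhs,
        outcome_label=outcome_label,
        n_matched=n_matched,
        n_matched_positive=n_matched_positive,
        n_positive_total=int((y == 1).sum()),
    )


def mine_class_association_rules(
    items_table: pd.DataFrame,
    outcome_column: str,
    constraints: MiningConstraints = MiningConstraints(),
    dmap: DiscretizationMap | None = None,
    outcome_label: str | None = None,
) -> RuleSet:
    """Mine all rules ``LHS -> poor outcome`` satisfying the constraints.

    ``items_table`` must be fully discretized (categorical/binned columns plus
    the binary outcome column).  When ``dmap`` is given, binned columns emit
    interval items that match raw continuous patient values; all other columns
    emit equals-items.
    """
    if outcome_column not in items_table.columns:
        raise KeyError(f"outcome column {outcome_column!r} not in table")
    features = items_table.drop(columns=[outcome_column])
    _check_discretized(features)
    y = pd.to_numeric(items_table[outcome_column]).to_numpy()
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("no positive class: cannot mine poor-outcome rules")
    label = outcome_label if outcome_label is not None else "1"

    items, masks = _build_item_universe(features, dmap)
    pos_rows = y == 1
    pos_masks = [m[pos_rows] for m in masks]
    min_pos_count = constraints.min_commonality * n_pos - _EPS

    # Level 1: frequent single items among positives.
    frequent: dict[tuple[int, ...], np.ndarray] = {}
    for i, pm in enumerate(pos_masks):
        if pm.sum() >= min_pos_count:
            frequent[(i,)] = pm
    all_frequent = dict(frequent)

    level = frequent
    for _ in range(2, constraints.max_items + 1):
        if not level:
            break
        next_level: dict[tuple[int, ...], np.ndarray] = {}
        keys = sorted(level)
        for a_idx, key_a in enumerate(keys):
            for key_b in keys[a_idx + 1 :]:
                if key_a[:-1] != key_b[:-1]:
                    break  # sorted prefixes: no further joins for key_a
                i, j = key_a[-1], key_b[-1]
                if items[i].feature_name == items[j].feature_name:
                    continue
                candidate = key_a + (j,)
                # Apriori pruning: all (k-1)-subsets must be frequent.
                if any(
                    candidate[:m] + candidate[m + 1 :] not in level
                    for m in range(len(candidate) - 1)
                ):
                    continue
                mask = level[key_a] & pos_masks[j]
                if mask.sum() >= min_pos_count:
                    next_level[candidate] = mask
        all_frequent.update(next_level)
        level = next_level

    rules = []
    for key in all_frequent:
        rule = _make_rule(key, items, masks, y, label)
        if rule.confidence >= constraints.min_confidence - _EPS:
            rules.append(rule)
    return RuleSet(
        rules=_canonical_sort(rules),
        provenance=constraints.as_dict(),
        n_positive_total=n_pos,
    )


def enumerate_rules_bruteforce(
    items_table: pd.DataFrame,
    outcome_column: str,
    constraints: MiningConstraints = MiningConstraints(),
    dmap: DiscretizationMap | None = None,
    outcome_label: str | None = None,
) -> RuleSet:
    """Exhaustive subset enumeration with the same filters; the test oracle.

    Refuses tables whose item universe exceeds a small guard limit — this
    routine exists to check the miner on tiny fixtures, not to mine.
    """
    if len(items_table) == 0:
        raise ValueError("empty table")
    if outcome_column not in items_table.columns:
        raise KeyError(f"outcome column {outcome_column!r} not in table")
    features = items_table.drop(columns=[outcome_column])
    _check_discretized(features)
    y = pd.to_numeric(items_table[outcome_column]).to_numpy()
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("no positive class: cannot mine poor-outcome rules")
    label = outcome_label if outcome_label is not None else "1"

    items, masks = _build_item_universe(features, dmap)
    if len(items) > _BRUTEFORCE_ITEM_LIMIT:
        raise ValueError(
            f"{len(items)} distinct items exceed the brute-force guard "
            f"({_BRUTEFORCE_ITEM_LIMIT}); use mine_class_association_rules"
        )
    rules = []
    for size in range(1, constraints.max_items + 1):
        for combo in combinations(range(len(items)), size):
            feats = [items[i].feature_name for i in combo]
            if len(set(feats)) != size:
                continue
            full = np.logical_and.reduce([masks[i] for i in combo])
            n_matched = int(full.sum())
            if n_matched == 0:
                continue
            rule = _make_rule(combo, items, masks, y, label)
            if (
                rule.commonality >= constraints.min_commonality - _EPS
                and rule.confidence >= constraints.min_confidence - _EPS
            ):
                rules.append(rule)
    return RuleSet(
        rules=_canonical_sort(rules),
        provenance=constraints.as_dict(),
        n_positive_total=n_pos,
    )


def filter_rules(ruleset: RuleSet, constraints: MiningConstraints) -> RuleSet:
    """Retain rules meeting all thresholds (inclusive comparisons)."""
    kept = [
        r
        for r in ruleset.rules
        if r.commonality >= constraints.min_commonality - _EPS
        and r.confidence >= constraints.min_confidence - _EPS
        and r.n_items <= constraints.max_items
    ]
    return RuleSet(
        rules=kept,
        provenance=constraints.as_dict(),
        n_positive_total=ruleset.n_positive_total,
    )
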