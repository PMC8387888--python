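"""Synthetic rare-outcome cohorts with planted rule structure.

No real clinical data ship with this package.  The generator emulates the
shape of an administrative/clinical feature table — mixed continuous,
categorical and binary features, a binary poor-outcome column at ~1.5%
prevalence, and an index-year column for a temporal train/test split — and
plants class association rules with known target confidence and commonality
so that mining, explanation, ranking and the sensitivity protocol can be
validated against ground truth.

Planting works at the item level: each planted rule owns dedicated
categorical levels that never occur in the background distribution.  For a
rule with target commonality s and confidence c, round(s * n_pos) positive
rows and the matching number of negative rows receive the rule's
feature-value items, so realized confidence/commonality deviate from the
targets only through rounding and row-selection overlap.  Ground truth
reports the realized counts from a final scan of the table.  Several default
planted rules share items, giving the top ranks the redundancy that the
diversity term exists to penalize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .explain import InterventionCatalog
from .rule_model import AssociationRule, FeatureValueItem, RuleSet

__all__ = [
    "PlantedRule",
    "SyntheticCohortSpec",
    "CohortGroundTruth",
    "generate_cohort",
    "summarize_cohort",
    "make_catalog",
]


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth pattern: equals-items plus target confidence/commonality."""

    name: str
    items: tuple[tuple[str, str], ...]  # (feature, planted level)
    confidence: float
    commonality: float

    def __post_init__(self) -> None:
        if not 0 < self.confidence <= 1:
            raise ValueError(f"planted rule {self.name}: confidence must be in (0, 1]")
        if not 0 < self.commonality <= 1:
            raise ValueError(f"planted rule {self.name}: commonality must be in (0, 1]")
        if not 1 <= len(self.items) <= 5:
            raise ValueError(f"planted rule {self.name}: 1..5 items required")

    @property
    def item_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.items)


def _default_planted() -> tuple[PlantedRule, ...]:
    # Overlap-heavy by design: A/B/C share cat0=p0; E shares one item with
    # each of A and B.  F fails the 50% confidence threshold, G the 1%
    # commonality threshold — mining must recover A-E and never F or G.
    return (
        PlantedRule("A", (("cat0", "p0"), ("cat1", "p1")), 0.75, 0.08),
        PlantedRule("B", (("cat0", "p0"), ("cat2", "p2")), 0.65, 0.06),
        PlantedRule("C", (("cat0", "p0"), ("cat3", "p3")), 0.60, 0.05),
        PlantedRule("D", (("cat4", "p4"),), 0.70, 0.07),
        PlantedRule("E", (("cat1", "p1"), ("cat2", "p2")), 0.55, 0.04),
        PlantedRule("F", (("cat5", "p5"),), 0.30, 0.05),
        PlantedRule("G", (("cat6", "p6"),), 0.60, 0.004),
    )


@dataclass
class SyntheticCohortSpec:
    """Generator parameters; the defaults are the cohort the tests study.

    30 features (15 continuous, 10 categorical, 5 binary), 20,000
    patient-period instances at 1.5% poor-outcome prevalence, index years
    2011-2018 for the temporal split.  Three continuous features are
    outcome-linked (positives shifted upward) so supervised discretization
    has real signal to find.
    """

    n_instances: int = 20000
    outcome_prevalence: float = 0.015
    n_continuous: int = 15
    n_categorical: int = 10
    n_binary: int = 5
    n_categorical_levels: int = 8
    binary_positive_rate: float = 0.3
    outcome_shifts: tuple[float, ...] = (1.0, 0.8, 0.5)  # in SD units, first features
    missing_rate: float = 0.02  # continuous features only
    year_range: tuple[int, int] = (2011, 2018)
    planted_rules: tuple[PlantedRule, ...] = field(default_factory=_default_planted)
    actionable_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be positive")
        if not 0 < self.outcome_prevalence < 1:
            raise ValueError("outcome_prevalence must be in (0, 1)")
        if not 0 <= self.actionable_fraction <= 1:
            raise ValueError("actionable_fraction must be in [0, 1]")
        cat_features = {f"cat{i}" for i in range(self.n_categorical)}
        level_by_feature: dict[str, str] = {}
        rule_sets = {}
        for rule in self.planted_rules:
            for feature, level in rule.items:
                if feature not in cat_features:
                    raise ValueError(
                        f"planted rule {rule.name}: {feature!r} is not a categorical feature"
                    )
                prior = level_by_feature.setdefault(feature, level)
                if prior != level:
                    raise ValueError(
                        f"feature {feature!r} planted with two levels ({prior!r}, {level!r}); "
                        "planted levels must be unique per feature"
                    )
            rule_sets[rule.name] = rule.item_set
        names = sorted(rule_sets)
        for a in names:
            for b in names:
                if a != b and rule_sets[a] < rule_sets[b]:
                    raise ValueError(
                        f"planted rule {a} is a subset of {b}; planting would inflate its counts"
                    )


@dataclass
class CohortGroundTruth:
    """Planted rules with realized (scanned) counts, plus cohort totals."""

    n_instances: int
    n_positive: int
    planted: list[dict]

    def realized(self, name: str) -> dict:
        for rec in self.planted:
            if rec["name"] == name:
                return rec
        raise KeyError(name)


def _plant(
    df: pd.DataFrame,
    y: np.ndarray,
    rule: PlantedRule,
    rng: np.random.Generator,
) -> None:
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    n_pos_target = int(round(rule.commonality * pos_idx.size))
    if n_pos_target < 1:
        raise ValueError(
            f"planted rule {rule.name}: commonality target {rule.commonality} "
            f"yields no positive rows at n_pos={pos_idx.size}"
        )
    n_matched_target = int(round(n_pos_target / rule.confidence))
    n_neg_target = n_matched_target - n_pos_target
    if n_pos_target > pos_idx.size or n_neg_target > neg_idx.size:
        raise ValueError(f"planted rule {rule.name}: targets infeasible for cohort size")
    chosen_pos = rng.choice(pos_idx, size=n_pos_target, replace=False)
    chosen_neg = rng.choice(neg_idx, size=n_neg_target, replace=False)
    rows = np.concatenate([chosen_pos, chosen_neg])
    for feature, level in rule.items:
        df.loc[rows, feature] = level


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """Draw a cohort table and its ground truth; fully seed-deterministic."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    y = (rng.random(n) < spec.outcome_prevalence).astype(int)

    data: dict[str, np.ndarray | pd.Series] = {}
    data["instance_id"] = np.array([f"pt{i:06d}" for i in range(n)])
    data["index_year"] = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=n)

    for j in range(spec.n_continuous):
        mu, sd = 10.0 * j, 1.0 + 0.25 * j
        col = rng.normal(mu, sd, size=n)
        if j < len(spec.outcome_shifts):
            col = col + spec.outcome_shifts[j] * sd * y
        if spec.missing_rate > 0:
            col[rng.random(n) < spec.missing_rate] = np.nan
        data[f"cont{j:02d}"] = col

    base_levels = [chr(ord("a") + k) for k in range(spec.n_categorical_levels)]
    for j in range(spec.n_categorical):
        data[f"cat{j}"] = rng.choice(base_levels, size=n)
    for j in range(spec.n_binary):
        data[f"bin{j}"] = (rng.random(n) < spec.binary_positive_rate).astype(int)

    df = pd.DataFrame(data)
    df["outcome"] = y

    for rule in spec.planted_rules:
        _plant(df, y, rule, rng)

    n_pos = int(y.sum())
    planted_records = []
    for rule in spec.planted_rules:
        mask = np.ones(n, dtype=bool)
        for feature, level in rule.items:
            mask &= (df[feature] == level).to_numpy()
        n_matched = int(mask.sum())
        n_matched_pos = int((mask & (y == 1)).sum())
        planted_records.append(
            {
                "name": rule.name,
                "items": [list(it) for it in rule.items],
                "target_confidence": rule.confidence,
                "target_commonality": rule.commonality,
                "n_matched": n_matched,
                "n_matched_positive": n_matched_pos,
                "realized_confidence": n_matched_pos / n_matched if n_matched else 0.0,
                "realized_commonality": n_matched_pos / n_pos if n_pos else 0.0,
            }
        )
    truth = CohortGroundTruth(n_instances=n, n_positive=n_pos, planted=planted_records)
    return df, truth


def summarize_cohort(df: pd.DataFrame, outcome_column: str = "outcome") -> dict:
    """Prevalence, per-feature missingness and item frequencies."""
    if outcome_column not in df.columns:
        raise KeyError(f"outcome column {outcome_column!r} not in table")
    from .predictor_eval import prevalence

    n = len(df)
    n_pos = int(pd.to_numeric(df[outcome_column]).sum())
    feature_cols = [c for c in df.columns if c not in (outcome_column, "instance_id")]
    missingness = {c: float(100.0 * df[c].isna().mean()) for c in feature_cols}
    item_freq: dict[str, dict[str, int]] = {}
    for c in feature_cols:
        if not pd.api.types.is_float_dtype(df[c]):
            item_freq[c] = {str(k): int(v) for k, v in df[c].value_counts().items()}
    return {
        "n_instances": n,
        "n_positive": n_pos,
        "prevalence_pct": prevalence(n_pos, n) if n else 0.0,
        "missingness_pct": missingness,
        "item_frequencies": item_freq,
    }


def make_catalog(
    ruleset: RuleSet, actionable_fraction: float = 1.0, seed: int = 0
) -> InterventionCatalog:
    """Synthetic intervention catalog over a rule set's item universe.

    A seeded fraction of the distinct items receive one placeholder
    intervention text each; the rest get none (and stay nonactionable).
    """
    if not 0 <= actionable_fraction <= 1:
        raise ValueError("actionable_fraction must be in [0, 1]")
    universe = sorted({p.item_key for r in ruleset.rules for p in r.lhs})
    rng = np.random.default_rng(seed)
    n_actionable = int(round(actionable_fraction * len(universe)))
    chosen = set(rng.choice(len(universe), size=n_actionable, replace=False).tolist())
    entries = {
        key: ([f"synthetic intervention for {key}"] if i in chosen else [])
        for i, key in enumerate(universe)
    }
    return InterventionCatalog(entries=entries)
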