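from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rulerank import (
    AssociationRule,
    FeatureValueItem,
    MiningConstraints,
    SyntheticCohortSpec,
    generate_cohort,
    mine_class_association_rules,
)
from rulerank.discretize import apply_discretization, fit_discretization
from rulerank.pipeline import temporal_split


def make_item(feature: str, value: str = "x", actionable: bool = True) -> FeatureValueItem:
    return FeatureValueItem(
        feature_name=feature,
        condition_kind="equals",
        category_value=value,
        actionable=actionable,
    )


def make_rule(
    features,
    confidence: float,
    commonality: float,
    n_matched_positive: int,
    actionable: bool = True,
    value: str = "x",
) -> AssociationRule:
    """Build a rule whose counts realize the requested fractions exactly."""
    n_matched = round(n_matched_positive / confidence)
    n_positive_total = round(n_matched_positive / commonality)
    assert abs(n_matched_positive / n_matched - confidence) < 1e-12
    assert abs(n_matched_positive / n_positive_total - commonality) < 1e-12
    return AssociationRule(
        lhs=tuple(make_item(f, value, actionable) for f in features),
        outcome_label="1",
        n_matched=n_matched,
        n_matched_positive=n_matched_positive,
        n_positive_total=n_positive_total,
    )


@pytest.fixture
def three_rule_pool():
    """The worked ranking pool: r1{A,B} C=.8 S=.04, r2{A,C} C=.6 S=.02, r3{D} C=.5 S=.01."""
    r1 = make_rule(["A", "B"], 0.8, 0.04, n_matched_positive=4)
    r2 = make_rule(["A", "C"], 0.6, 0.02, n_matched_positive=3)
    r3 = make_rule(["D"], 0.5, 0.01, n_matched_positive=1)
    return [r1, r2, r3]


def random_rule_pool(rng: np.random.Generator, q: int, n_features: int = 12):
    """A random pool of rules for property/oracle tests."""
    rules = []
    for _ in range(q):
        m = int(rng.integers(1, 6))
        feats = rng.choice(n_features, size=m, replace=False)
        conf_num = int(rng.integers(1, 21))
        conf_den = int(rng.integers(conf_num, 41))
        npos = 200
        nmp = int(rng.integers(1, npos // 2))
        rules.append(
            AssociationRule(
                lhs=tuple(
                    make_item(f"F{f}", actionable=bool(rng.random() < 0.6))
                    for f in sorted(feats)
                ),
                outcome_label="1",
                n_matched=round(nmp * conf_den / conf_num),
                n_matched_positive=nmp,
                n_positive_total=npos,
            )
        )
    return rules


@pytest.fixture(scope="session")
def mined_cohort():
    """Full-scale study cohort: generate, temporal split, discretize, mine.

    Session-scoped because mining at n = 20,000 takes ~30 s; every consumer
    treats the contents as read-only.
    """
    spec = SyntheticCohortSpec(seed=7)
    df, truth = generate_cohort(spec)
    train, test = temporal_split(df, "index_year", 2018, 0.8, 7)
    feature_cols = [
        c for c in df.columns if c not in ("outcome", "instance_id", "index_year")
    ]
    continuous = [c for c in feature_cols if df[c].dtype.kind == "f"]
    dmap = fit_discretization(
        train[feature_cols], train["outcome"].to_numpy(), continuous
    )
    items = apply_discretization(train[feature_cols], dmap)
    items_table = items.copy()
    items_table["outcome"] = train["outcome"].to_numpy()
    ruleset = mine_class_association_rules(
        items_table, "outcome", MiningConstraints(), dmap=dmap
    )
    return {
        "spec": spec,
        "df": df,
        "truth": truth,
        "train": train,
        "test": test,
        "feature_cols": feature_cols,
        "dmap": dmap,
        "ruleset": ruleset,
    }
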