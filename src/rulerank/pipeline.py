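"""End-to-end orchestration: discretize -> mine -> predict -> explain -> rank.

Each stage writes its artifact to disk and can be rerun independently; the
whole run is deterministic given the configuration seed.  The train/test
split is temporal when an index-period column is available (mirroring a
train-on-past, test-on-latest-year design), otherwise a seeded random
fraction.

The bundled risk model is a plain logistic regression on one-hot encoded
discretized features.  It exists so demos and tests have a score column to
binarize; any external classifier's scores can be supplied instead, and the
explanation stages never look at anything but the predicted-positive flags.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discretize import DiscretizationMap, apply_discretization, fit_discretization
from .explain import InterventionCatalog, attach_interventions, find_applicable_rules
from .predictor_eval import ConfusionCounts, binarize_top_fraction, confusion_metrics, prevalence
from .ranking import RankingConfig, rank_rules, select_top
from .rule_mining import MiningConstraints, mine_class_association_rules
from .rule_model import (
    RuleSet,
    instances_from_frame,
    read_rules,
    write_rules,
)
from .synthetic_data import SyntheticCohortSpec, generate_cohort, make_catalog

logger = logging.getLogger("rulerank")

__all__ = ["PipelineConfig", "run_end_to_end", "temporal_split", "score_with_reference_classifier"]


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; round-trips through YAML."""

    data_path: str | None = None  # None -> generate the default synthetic cohort
    catalog_path: str | None = None  # None -> synthetic catalog
    out_dir: str = "rulerank_run"
    outcome_column: str = "outcome"
    id_column: str = "instance_id"
    period_column: str | None = "index_year"
    test_period: int = 2018
    train_fraction: float = 0.8  # used only without a period column
    cutoff_fraction: float = 0.10
    actionable_fraction: float = 1.0
    mining: MiningConstraints = field(default_factory=MiningConstraints)
    ranking: RankingConfig = field(default_factory=RankingConfig)
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        mining = MiningConstraints(**payload.pop("mining", {}))
        ranking = RankingConfig(**payload.pop("ranking", {}))
        return cls(mining=mining, ranking=ranking, **payload)


def temporal_split(
    df: pd.DataFrame,
    period_column: str | None,
    test_period,
    train_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/test split: by period when available, else a seeded fraction."""
    if period_column is not None and period_column in df.columns:
        test_mask = df[period_column] == test_period
        if not test_mask.any():
            raise ValueError(f"no rows with {period_column} == {test_period}")
        return df[~test_mask].copy(), df[test_mask].copy()
    rng = np.random.default_rng(seed)
    train_mask = rng.random(len(df)) < train_fraction
    return df[train_mask].copy(), df[~train_mask].copy()


def _one_hot(items_df: pd.DataFrame) -> pd.DataFrame:
    return pd.get_dummies(items_df.astype("object"), dummy_na=True)


def score_with_reference_classifier(
    train_items: pd.DataFrame,
    train_outcome: pd.Series,
    test_items: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Risk scores from the bundled logistic-regression reference classifier."""
    from sklearn.linear_model import LogisticRegression

    x_train = _one_hot(train_items)
    x_test = _one_hot(test_items).reindex(columns=x_train.columns, fill_value=0)
    model = LogisticRegression(max_iter=500, random_state=seed)
    model.fit(x_train.to_numpy(dtype=float), train_outcome.to_numpy(dtype=int))
    return model.predict_proba(x_test.to_numpy(dtype=float))[:, 1]


def _continuous_features(df: pd.DataFrame, skip: set[str]) -> list[str]:
    return [
        c
        for c in df.columns
        if c not in skip and pd.api.types.is_float_dtype(df[c])
    ]


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run every stage, writing each artifact under ``config.out_dir``.

    Returns the run report (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # --- data -------------------------------------------------------------
    t0 = stage("data")
    if config.data_path is None:
        spec = SyntheticCohortSpec(seed=config.seed)
        df, truth = generate_cohort(spec)
        df.to_csv(out / "cohort.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
    else:
        df = pd.read_csv(config.data_path)
    if config.outcome_column not in df.columns:
        raise RuntimeError(f"stage data: outcome column {config.outcome_column!r} missing")
    train_df, test_df = temporal_split(
        df, config.period_column, config.test_period, config.train_fraction, config.seed
    )
    report["stages"]["data"] = {
        "n_train": len(train_df),
        "n_test": len(test_df),
        "train_prevalence_pct": prevalence(
            int(train_df[config.outcome_column].sum()), len(train_df)
        ),
        "test_prevalence_pct": prevalence(
            int(test_df[config.outcome_column].sum()), len(test_df)
        ),
    }
    logger.info("data: %.2fs", time.perf_counter() - t0)

    skip = {config.outcome_column, config.id_column}
    if config.period_column:
        skip.add(config.period_column)
    feature_cols = [c for c in df.columns if c not in skip]

    # --- discretize (train split only) ------------------------------------
    t0 = stage("discretize")
    continuous = _continuous_features(train_df[feature_cols], set())
    dmap = fit_discretization(
        train_df[feature_cols], train_df[config.outcome_column].to_numpy(), continuous
    )
    dmap.to_json(out / "discretization.json")
    train_items = apply_discretization(train_df[feature_cols], dmap)
    report["stages"]["discretize"] = {
        "n_continuous": len(continuous),
        "n_with_cuts": sum(1 for c in dmap.cut_points.values() if c),
    }
    logger.info("discretize: %.2fs", time.perf_counter() - t0)

    # --- mine --------------------------------------------------------------
    t0 = stage("mine")
    items_table = train_items.copy()
    items_table[config.outcome_column] = train_df[config.outcome_column].to_numpy()
    ruleset = mine_class_association_rules(
        items_table, config.outcome_column, config.mining, dmap=dmap
    )
    report["stages"]["mine"] = {"n_rules": len(ruleset)}
    logger.info("mine: %d rules, %.2fs", len(ruleset), time.perf_counter() - t0)

    # --- interventions -----------------------------------------------------
    if config.catalog_path is not None:
        catalog = InterventionCatalog.load(config.catalog_path)
    else:
        catalog = make_catalog(ruleset, config.actionable_fraction, config.seed)
        with open(out / "catalog.json", "w") as fh:
            json.dump(catalog.entries, fh, indent=1, sort_keys=True)
    catalog.validate_against(ruleset)
    ruleset = RuleSet(
        rules=[attach_interventions(r, catalog) for r in ruleset.rules],
        provenance=ruleset.provenance,
        n_positive_total=ruleset.n_positive_total,
    )
    write_rules(ruleset, out / "rules.json")

    # --- score & binarize ---------------------------------------------------
    t0 = stage("predict")
    test_items = apply_discretization(test_df[feature_cols], dmap)
    scores = score_with_reference_classifier(
        train_items, train_df[config.outcome_column], test_items, config.seed
    )
    predicted = binarize_top_fraction(scores, config.cutoff_fraction)
    counts = ConfusionCounts.from_labels(
        test_df[config.outcome_column].to_numpy(), predicted
    )
    metrics = confusion_metrics(counts)
    scored = test_df.copy()
    scored["risk_score"] = scores
    scored["predicted_positive"] = predicted.astype(int)
    scored.to_csv(out / "scored_test.csv", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(
            {"counts": dataclasses.asdict(counts), "metrics": metrics},
            fh,
            indent=1,
            sort_keys=True,
        )
    report["stages"]["predict"] = {
        "n_predicted_positive": int(predicted.sum()),
        "metrics": metrics,
    }
    logger.info("predict: %.2fs", time.perf_counter() - t0)

    # --- explain & rank -----------------------------------------------------
    t0 = stage("explain+rank")
    instances = instances_from_frame(
        scored,
        outcome_column=config.outcome_column,
        id_column=config.id_column if config.id_column in scored.columns else None,
        risk_score_column="risk_score",
        predicted_column="predicted_positive",
    )
    ranked_out = []
    n_explained = 0
    for inst in instances:
        if inst.predicted_positive is not True:
            continue
        expl = find_applicable_rules(inst, ruleset)
        record = {"instance_id": inst.instance_id, "q": expl.q, "top_rules": []}
        if expl.q >= 1:
            n_explained += 1
            ranked = rank_rules(expl, config.ranking)
            for sr in select_top(ranked, config.ranking.n):
                record["top_rules"].append(
                    {
                        "rank": sr.rank,
                        "score": sr.score,
                        "confidence": sr.rule.confidence,
                        "commonality": sr.rule.commonality,
                        "items": [si.item.item_key for si in sr.sorted_items],
                        "interventions": list(sr.rule.interventions),
                    }
                )
        ranked_out.append(record)
    with open(out / "ranked_explanations.json", "w") as fh:
        json.dump(ranked_out, fh, indent=1, sort_keys=True)
    report["stages"]["explain_rank"] = {
        "n_predicted_positive": int(predicted.sum()),
        "n_explained": n_explained,
    }
    logger.info("explain+rank: %.2fs", time.perf_counter() - t0)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
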