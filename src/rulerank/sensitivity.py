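"""Parameter sensitivity protocol for the rule scoring function.

One ranking parameter at a time is moved across a grid while the others stay
at their defaults; for every eligible patient (predicted positive with at
least one applicable rule) the unique feature-value items in the top
min(3, q) rules are compared between the default and the modified
configuration.  The per-value summary is the average percentage change in
those unique items.

Only w_c, w_s, w_n, w_d and d are swept: w_a (and the item weights w_g, w_b)
only separate actionable from nonactionable entries without affecting order
within each group, so sweeping them is not informative.

"Changed unique items" defaults to the items of the baseline top set that
the variant top set lost, normalized by the baseline set size — this keeps
the metric in [0, 100].  A symmetric-difference reading is available as a
mode switch.  Both rankings use the same seed so that only the parameter
change, never tie-break noise, drives the metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .explain import ExplanationSet, find_applicable_rules
from .ranking import SWEEPABLE_PARAMETERS, RankingConfig, ScoredRule, rank_rules
from .rule_model import PatientInstance, RuleSet

__all__ = [
    "SweepResult",
    "unique_items_top",
    "percent_item_change",
    "sweep_parameter",
]


def unique_items_top(ranked: Sequence[ScoredRule], limit: int = 3) -> frozenset[str]:
    """Union of LHS item keys over the top min(limit, q) ranked rules."""
    if not len(ranked):
        raise ValueError("ranked list is empty")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    keys: set[str] = set()
    for sr in ranked[:limit]:
        keys |= sr.rule.item_keys
    return frozenset(keys)


def percent_item_change(
    baseline: frozenset[str] | set[str],
    variant: frozenset[str] | set[str],
    mode: str = "baseline_loss",
) -> float:
    """100 x changed unique items / baseline unique items.

    ``baseline_loss`` counts baseline items missing from the variant;
    ``symmetric`` counts the symmetric difference (can exceed 100).
    """
    if not baseline:
        raise ValueError("baseline item set is empty")
    if mode == "baseline_loss":
        changed = len(set(baseline) - set(variant))
    elif mode == "symmetric":
        changed = len(set(baseline) ^ set(variant))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * changed / len(baseline)


@dataclass
class SweepResult:
    parameter: str
    grid: list[float]
    avg_pct_change: list[float]  # per-patient percentages, averaged
    aggregate_pct_change: list[float]  # pooled numerator / pooled denominator
    n_patients: int
    per_patient: dict[float, list[float]] = field(default_factory=dict)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "value": self.grid,
                "avg_pct_change": self.avg_pct_change,
                "aggregate_pct_change": self.aggregate_pct_change,
            }
        )


def _explanations(
    patients: Iterable, ruleset: RuleSet | None
) -> list[ExplanationSet]:
    expls = []
    for p in patients:
        if isinstance(p, ExplanationSet):
            expl = p
        elif isinstance(p, PatientInstance):
            if ruleset is None:
                raise ValueError("a RuleSet is required when passing raw instances")
            if p.predicted_positive is not True:
                continue
            expl = find_applicable_rules(p, ruleset)
        else:
            raise TypeError(f"cannot sweep over {type(p).__name__}")
        if expl.q >= 1:
            expls.append(expl)
    return expls


def sweep_parameter(
    patients: Iterable,
    ruleset: RuleSet | None,
    cfg: RankingConfig,
    parameter: str,
    grid: Sequence[float],
    limit: int = 3,
    mode: str = "baseline_loss",
) -> SweepResult:
    """Vary one parameter over a grid, others at their configured values.

    ``patients`` may be PatientInstance objects (predicted positives are
    explained against ``ruleset``; patients with q = 0 are ineligible) or
    precomputed ExplanationSets.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"parameter {parameter!r} is not swept; choose one of {SWEEPABLE_PARAMETERS}"
        )
    expls = _explanations(patients, ruleset)
    if not expls:
        raise ValueError("no eligible patient (predicted positive with q >= 1)")

    baselines = {
        e.instance_id: unique_items_top(rank_rules(e, cfg), limit) for e in expls
    }
    grid = [float(v) for v in grid]
    avg, agg = [], []
    per_patient: dict[float, list[float]] = {}
    for value in grid:
        variant_cfg = cfg.with_param(parameter, value)
        changes = []
        pooled_num = 0
        pooled_den = 0
        for e in expls:
            base = baselines[e.instance_id]
            var = unique_items_top(rank_rules(e, variant_cfg), limit)
            changes.append(percent_item_change(base, var, mode))
            lost = len(set(base) - set(var)) if mode == "baseline_loss" else len(
                set(base) ^ set(var)
            )
            pooled_num += lost
            pooled_den += len(base)
        per_patient[value] = changes
        avg.append(sum(changes) / len(changes))
        agg.append(100.0 * pooled_num / pooled_den)
    return SweepResult(
        parameter=parameter,
        grid=grid,
        avg_pct_change=avg,
        aggregate_pct_change=agg,
        n_patients=len(expls),
        per_patient=per_patient,
    )
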