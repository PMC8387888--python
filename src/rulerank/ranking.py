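"""Diversified ranking of a patient's rule-based explanations.

This is the heart of the package.  The rules found for one patient are ranked
greedily; at the k-th step each still-unranked rule r carries the score

    score_r = w_c * norm(C_r) + w_s * norm(log10 S_r) - w_n * norm(N_r)
              + w_d * mean_i exp(-d * t_i) + w_a * 1[r actionable]

where C_r is confidence, S_r commonality, N_r the LHS length, and t_i counts
how many of the top k-1 rules contain item p_i.  norm() is min-max over the
patient's full initial rule pool and is frozen for the whole process, so
between iterations a score changes only through the exponential-decay
diversity term.  The rule with the highest score is ranked next; exact score
ties are broken randomly by the seeded generator owned by the call.

Commonality is log10-transformed before normalization because commonality
values are heavily right-skewed; min-max normalization absorbs the additive
constant, so storing commonality as a fraction or a percentage gives
identical scores.

Once a rule's rank is decided, the items on its LHS are sorted by

    score_p = w_g * exp(-d * t) + w_b * 1[p actionable]

with t again counted over the top k-1 rules (not the current rule), and ties
shuffled by the same generator.  Defaults: w_c = w_s = w_n = 1, w_d = 50,
w_a = 100, w_g = 1, w_b = 2, d = 5, n = 3 displayed rules.  With w_a >
w_c + w_s + w_n + w_d every actionable rule outscores every nonactionable
one; w_b > w_g does the same for items.
"""

from __future__ import annotations

import math
import random
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .rule_model import AssociationRule, FeatureValueItem

__all__ = [
    "RankingConfig",
    "Normalizer",
    "ScoredItem",
    "ScoredRule",
    "make_normalizer",
    "diversity_term",
    "score_rule",
    "score_item",
    "sort_rule_items",
    "rank_rules",
    "rank_rules_naive",
    "select_top",
]

SWEEPABLE_PARAMETERS = ("w_c", "w_s", "w_n", "w_d", "d")


@dataclass(frozen=True)
class RankingConfig:
    """All weights of the rule and item scoring functions.

    ``w_c``/``w_s``/``w_n`` weight confidence, log-commonality and LHS-length;
    ``w_d`` the diversity term and ``d`` its decay constant; ``w_a`` pushes
    actionable rules up.  ``w_g``/``w_b`` are the item-score analogues of
    ``w_d``/``w_a``.  ``n`` is how many top rules are displayed initially.
    """

    w_c: float = 1.0
    w_s: float = 1.0
    w_n: float = 1.0
    w_d: float = 50.0
    w_a: float = 100.0
    w_g: float = 1.0
    w_b: float = 2.0
    d: float = 5.0
    n: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_c", "w_s", "w_n", "w_d", "w_a", "w_g", "w_b", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be a positive integer")

    def with_param(self, name: str, value: float) -> "RankingConfig":
        if name not in ("w_c", "w_s", "w_n", "w_d", "w_a", "w_g", "w_b", "d", "n", "seed"):
            raise ValueError(f"unknown ranking parameter {name!r}")
        return replace(self, **{name: value})


@dataclass(frozen=True)
class Normalizer:
    """Frozen per-patient min-max ranges for the three normalized variables."""

    conf_min: float
    conf_max: float
    logcomm_min: float
    logcomm_max: float
    len_min: float
    len_max: float

    @staticmethod
    def _norm(x: float, lo: float, hi: float) -> float:
        if hi == lo:
            # all rules share this value; the variable carries no ranking signal
            return 0.0
        return (x - lo) / (hi - lo)

    def confidence(self, x: float) -> float:
        return self._norm(x, self.conf_min, self.conf_max)

    def log_commonality(self, s: float) -> float:
        return self._norm(math.log10(s), self.logcomm_min, self.logcomm_max)

    def length(self, m: int) -> float:
        return self._norm(m, self.len_min, self.len_max)


def make_normalizer(rules: Sequence[AssociationRule]) -> Normalizer:
    """Min-max ranges of C_r, log10(S_r) and N_r over the patient's q rules.

    Built once from the full pool and reused at every iteration; commonality
    must be positive (mining guarantees S_r >= min_commonality > 0).
    """
    if not rules:
        raise ValueError("cannot build a normalizer from an empty rule list")
    confs = [r.confidence for r in rules]
    logcomms = [math.log10(r.commonality) for r in rules]
    lengths = [r.n_items for r in rules]
    return Normalizer(
        conf_min=min(confs),
        conf_max=max(confs),
        logcomm_min=min(logcomms),
        logcomm_max=max(logcomms),
        len_min=min(lengths),
        len_max=max(lengths),
    )


def diversity_term(
    rule: AssociationRule, usage: Mapping[str, int], d: float
) -> float:
    """Mean over LHS items of exp(-d * t_i); in (0, 1], equal to 1 when all fresh."""
    return sum(math.exp(-d * usage.get(p.item_key, 0)) for p in rule.lhs) / rule.n_items


def score_rule(
    rule: AssociationRule,
    norm: Normalizer,
    usage: Mapping[str, int],
    cfg: RankingConfig,
) -> float:
    """The five-term rule score (note the minus sign on the length term)."""
    return (
        cfg.w_c * norm.confidence(rule.confidence)
        + cfg.w_s * norm.log_commonality(rule.commonality)
        - cfg.w_n * norm.length(rule.n_items)
        + cfg.w_d * diversity_term(rule, usage, cfg.d)
        + cfg.w_a * (1.0 if rule.actionable else 0.0)
    )


def score_item(
    item: FeatureValueItem, usage: Mapping[str, int], cfg: RankingConfig
) -> float:
    """The two-term item score: novelty decay plus actionability bonus."""
    t = usage.get(item.item_key, 0)
    return cfg.w_g * math.exp(-cfg.d * t) + cfg.w_b * (1.0 if item.actionable else 0.0)


@dataclass(frozen=True)
class ScoredItem:
    item: FeatureValueItem
    score: float
    rank: int  # 1-based within the rule


@dataclass(frozen=True)
class ScoredRule:
    rule: AssociationRule
    rank: int  # 1-based
    score: float  # selection-time score (the quantity the greedy step maximized)
    sorted_items: tuple[ScoredItem, ...]


def sort_rule_items(
    rule: AssociationRule,
    usage: Mapping[str, int],
    cfg: RankingConfig,
    rng: random.Random | None = None,
) -> tuple[ScoredItem, ...]:
    """Sort a displayed rule's LHS items by descending score_p.

    ``usage`` must reflect the top k-1 rules only (not the rule itself).
    Equal-scored items are ordered randomly and given consecutive ranks.
    """
    if rng is None:
        rng = random.Random(cfg.seed)
    scored = [(score_item(p, usage, cfg), p) for p in rule.lhs]
    groups: dict[float, list[FeatureValueItem]] = defaultdict(list)
    for s, p in scored:
        groups[s].append(p)
    out: list[ScoredItem] = []
    for s in sorted(groups, reverse=True):
        members = groups[s]
        if len(members) > 1:
            rng.shuffle(members)
        for p in members:
            out.append(ScoredItem(item=p, score=s, rank=len(out) + 1))
    return tuple(out)


def _rank(
    rules: Sequence[AssociationRule],
    cfg: RankingConfig,
    incremental: bool,
) -> list[ScoredRule]:
    if not len(rules):
        raise ValueError("nothing to rank: the patient has no applicable rules")
    rng = random.Random(cfg.seed)
    rules = list(rules)
    norm = make_normalizer(rules)
    usage: dict[str, int] = defaultdict(int)
    remaining = set(range(len(rules)))
    scores = {i: score_rule(rules[i], norm, usage, cfg) for i in remaining}
    prev_item_keys: frozenset[str] | None = None
    ranked: list[ScoredRule] = []
    while remaining:
        if incremental:
            if prev_item_keys is not None:
                # only the diversity term can change, and only for rules
                # sharing an item with the rule ranked in the previous step
                for i in remaining:
                    if rules[i].item_keys & prev_item_keys:
                        scores[i] = score_rule(rules[i], norm, usage, cfg)
        else:
            for i in remaining:
                scores[i] = score_rule(rules[i], norm, usage, cfg)
        best_score = max(scores[i] for i in remaining)
        candidates = sorted(i for i in remaining if scores[i] == best_score)
        chosen = candidates[0] if len(candidates) == 1 else rng.choice(candidates)
        rule = rules[chosen]
        items = sort_rule_items(rule, usage, cfg, rng)
        ranked.append(
            ScoredRule(rule=rule, rank=len(ranked) + 1, score=scores[chosen], sorted_items=items)
        )
        remaining.discard(chosen)
        for key in rule.item_keys:
            usage[key] += 1
        prev_item_keys = rule.item_keys
    return ranked


def rank_rules(rules_or_explanation, cfg: RankingConfig = RankingConfig()) -> list[ScoredRule]:
    """Greedy iterative ranking with incremental score updates.

    Accepts an :class:`~rulerank.explain.ExplanationSet` or a plain rule
    sequence.  At step k only rules sharing an item with the (k-1)-th ranked
    rule are rescored — by construction this yields exactly the scores of a
    full rescan.  One seeded generator drives all tie-breaks, consumed in a
    documented order: rule ties first, then item ties of the newly ranked
    rule.  A single rule short-circuits to rank 1.
    """
    rules = getattr(rules_or_explanation, "rules", rules_or_explanation)
    return _rank(rules, cfg, incremental=True)


def rank_rules_naive(
    rules_or_explanation, cfg: RankingConfig = RankingConfig()
) -> list[ScoredRule]:
    """Reference ranker that fully rescores every unranked rule each iteration.

    Exists as the cross-check for the incremental update rule; identical
    random-consumption order, so outputs must match :func:`rank_rules`
    exactly for every seed.
    """
    rules = getattr(rules_or_explanation, "rules", rules_or_explanation)
    return _rank(rules, cfg, incremental=False)


def select_top(ranked: Sequence[ScoredRule], n: int, offset: int = 0) -> list[ScoredRule]:
    """The first min(n, q) ranked rules (pagination via offset/limit)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    return list(ranked[offset : offset + n])
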