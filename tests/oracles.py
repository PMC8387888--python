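"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately written the slow, obvious way — plain loops,
no incremental updates, no pruning — so that agreement with the package is
evidence, not tautology.
"""

from __future__ import annotations

import math
import random
from collections import defaultdict
from itertools import combinations


# ---------------------------------------------------------------------------
# Greedy diversified ranking, fully rescored every iteration.


def naive_rank(rules, cfg):
    """Rank (rule, score) pairs by brute force.

    ``rules`` is a sequence of objects with .confidence, .commonality,
    .n_items, .actionable and .item_keys.  Tie-breaks consume one seeded
    generator in the documented order: rule ties first, then item-sort ties
    for the newly ranked rule (the item shuffle is replicated here only to
    keep the generator stream aligned; items themselves are not returned).
    """
    rng = random.Random(cfg.seed)
    q = len(rules)
    confs = [r.confidence for r in rules]
    logcomms = [math.log10(r.commonality) for r in rules]
    lens = [r.n_items for r in rules]

    def norm(x, lo, hi):
        return 0.0 if hi == lo else (x - lo) / (hi - lo)

    bounds = [
        (min(confs), max(confs)),
        (min(logcomms), max(logcomms)),
        (min(lens), max(lens)),
    ]
    usage: dict[str, int] = defaultdict(int)
    remaining = list(range(q))
    out = []
    while remaining:
        scores = {}
        for i in remaining:
            r = rules[i]
            decay = sum(math.exp(-cfg.d * usage[k]) for k in sorted(r.item_keys))
            scores[i] = (
                cfg.w_c * norm(confs[i], *bounds[0])
                + cfg.w_s * norm(logcomms[i], *bounds[1])
                - cfg.w_n * norm(lens[i], *bounds[2])
                + cfg.w_d * decay / r.n_items
                + cfg.w_a * (1.0 if r.actionable else 0.0)
            )
        best = max(scores[i] for i in remaining)
        ties = sorted(i for i in remaining if scores[i] == best)
        chosen = ties[0] if len(ties) == 1 else rng.choice(ties)
        # keep the rng stream aligned with the package's item-sort phase
        item_scores = defaultdict(list)
        for p in rules[chosen].lhs:
            s = cfg.w_g * math.exp(-cfg.d * usage[p.item_key]) + cfg.w_b * (
                1.0 if p.actionable else 0.0
            )
            item_scores[s].append(p)
        for s in sorted(item_scores, reverse=True):
            if len(item_scores[s]) > 1:
                rng.shuffle(item_scores[s])
        out.append((chosen, scores[chosen]))
        remaining.remove(chosen)
        for k in rules[chosen].item_keys:
            usage[k] += 1
    return out


# ---------------------------------------------------------------------------
# MDL-criterion discretization by exhaustive candidate evaluation.


def _entropy(labels):
    n = len(labels)
    if n == 0:
        return 0.0
    ent = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        ent -= p * math.log2(p)
    return ent


def mdlp_cuts_bruteforce(values, labels):
    """Recursive MDL-accepted cuts, evaluating every candidate midpoint."""
    pairs = sorted(zip(values, labels), key=lambda t: t[0])

    def split(pairs):
        n = len(pairs)
        labs = [l for _, l in pairs]
        if n < 2 or len(set(labs)) < 2:
            return []
        candidates = []
        for i in range(n - 1):
            if pairs[i][0] < pairs[i + 1][0]:
                candidates.append((pairs[i][0] + pairs[i + 1][0]) / 2.0)
        best_gain, best_cut = -math.inf, None
        for cut in candidates:
            left = [l for v, l in pairs if v <= cut]
            right = [l for v, l in pairs if v > cut]
            gain = (
                _entropy(labs)
                - len(left) / n * _entropy(left)
                - len(right) / n * _entropy(right)
            )
            if gain > best_gain + 1e-12:  # ties -> smallest cut
                best_gain, best_cut = gain, cut
        if best_cut is None:
            return []
        left = [(v, l) for v, l in pairs if v <= best_cut]
        right = [(v, l) for v, l in pairs if v > best_cut]
        k = len(set(labs))
        k1 = len(set(l for _, l in left))
        k2 = len(set(l for _, l in right))
        delta = (
            math.log2(3**k - 2)
            - k * _entropy(labs)
            + k1 * _entropy([l for _, l in left])
            + k2 * _entropy([l for _, l in right])
        )
        if best_gain <= (math.log2(n - 1) + delta) / n:
            return []
        return sorted([best_cut] + split(left) + split(right))

    return split(pairs)


# ---------------------------------------------------------------------------
# Class-association rules by exhaustive subset enumeration over row dicts.


def mine_rules_bruteforce(rows, outcome_key, min_comm, min_conf, max_items):
    """All rules as frozensets of (feature, value) with their counts.

    ``rows`` is a list of dicts; items are every observed (feature, value)
    pair other than the outcome.  Returns {itemset: (n_matched, n_pos)}.
    """
    universe = {
        (f, v)
        for row in rows
        for f, v in row.items()
        if f != outcome_key and v is not None
    }
    # an item matching every row carries no condition; the miner drops them too
    items = sorted(
        it for it in universe
        if sum(1 for row in rows if row.get(it[0]) == it[1]) < len(rows)
    )
    n_pos_total = sum(1 for row in rows if row[outcome_key] == 1)
    assert n_pos_total > 0
    out = {}
    for size in range(1, max_items + 1):
        for combo in combinations(items, size):
            if len({f for f, _ in combo}) != size:
                continue
            matched = [
                row for row in rows if all(row.get(f) == v for f, v in combo)
            ]
            if not matched:
                continue
            n_matched = len(matched)
            n_pos = sum(1 for row in matched if row[outcome_key] == 1)
            if (
                n_pos / n_pos_total >= min_comm - 1e-9
                and n_pos / n_matched >= min_conf - 1e-9
            ):
                out[frozenset(combo)] = (n_matched, n_pos)
    return out
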