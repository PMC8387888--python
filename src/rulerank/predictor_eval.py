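"""Model-agnostic coupling of any risk score to the explanation pipeline.

The upstream classifier is a black box: all the pipeline needs is a risk
score per instance.  Scores are binarized at a top-fraction cutoff (default:
the top 10% highest-risk instances are predicted positive) and standard
confusion-matrix metrics are reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "binarize_top_fraction",
    "confusion_metrics",
    "prevalence",
]


def binarize_top_fraction(risk_scores: Sequence[float], fraction: float) -> np.ndarray:
    """Flag exactly floor(fraction * N) highest-scoring instances as positive.

    Score ties at the boundary are broken by stable input order (earlier rows
    win), so the flagged count is exact for every input.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(risk_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    n_flag = int(np.floor(fraction * scores.size))
    predicted = np.zeros(scores.size, dtype=bool)
    if n_flag == 0:
        return predicted
    # stable sort on negated scores: descending by score, ascending by index
    order = np.argsort(-scores, kind="stable")
    predicted[order[:n_flag]] = True
    return predicted


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, actual: Sequence[int], predicted: Sequence[bool]) -> "ConfusionCounts":
        a = np.asarray(actual, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        if a.shape != p.shape:
            raise ValueError("actual and predicted must have equal length")
        return cls(
            tp=int((a & p).sum()),
            fp=int((~a & p).sum()),
            tn=int((~a & ~p).sum()),
            fn=int((a & ~p).sum()),
        )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and accuracy as percentages.

    A metric with a zero denominator is reported as None (undefined), not 0.
    """
    total = c.tp + c.fp + c.tn + c.fn
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "accuracy": _ratio(c.tp + c.tn, total),
    }


def prevalence(n_positive: int, n_total: int) -> float:
    """Outcome prevalence as a percentage: 100 * n_positive / n_total."""
    if n_total == 0:
        raise ZeroDivisionError("prevalence undefined for an empty cohort")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    return 100.0 * n_positive / n_total
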