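"""Supervised discretization with the entropy/MDL stopping rule.

Continuous features are converted to categorical bins before rule mining by
recursive binary splitting: at each node the candidate cut maximizing
information gain is found, and the split is accepted only when the gain beats
the minimum-description-length cost

    gain > [log2(N - 1) + log2(3^k - 2) - k*Ent(S) + k1*Ent(S1) + k2*Ent(S2)] / N

where ``k`` is the number of classes present in the node and ``k1``/``k2``
those of the two halves.  Fitting is univariate per feature.  Bins are
left-open/right-closed ``(low, high]``, with the first bin ``(-inf, c1]`` and
the last ``(c_last, +inf)``, so a value equal to a cut point falls in the
lower bin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rule_model import FeatureValueItem

__all__ = ["DiscretizationMap", "mdlp_cut_points", "fit_discretization", "apply_discretization"]


def _entropy(labels: np.ndarray) -> float:
    """Shannon entropy (base 2) of a binary/int label vector."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-np.sum(p * np.log2(p)))


def _n_classes(labels: np.ndarray) -> int:
    return int(np.unique(labels).size)


def _accept_split(labels: np.ndarray, left: np.ndarray, right: np.ndarray, gain: float) -> bool:
    n = labels.size
    k = _n_classes(labels)
    k1 = _n_classes(left)
    k2 = _n_classes(right)
    delta = (
        math.log2(3**k - 2)
        - k * _entropy(labels)
        + k1 * _entropy(left)
        + k2 * _entropy(right)
    )
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def _binary_entropy(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized entropy of two-class count pairs (pos, n - pos)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = pos / n
        q = 1.0 - p
        h = -(np.where(p > 0, p * np.log2(p), 0.0) + np.where(q > 0, q * np.log2(q), 0.0))
    return np.where(n > 0, h, 0.0)


def _best_cut(values: np.ndarray, labels: np.ndarray) -> tuple[float, float] | None:
    """Return (cut, gain) maximizing information gain, or None if no candidate.

    Candidate cuts are midpoints between adjacent distinct sorted values.
    Gain ties (within 1e-12) are resolved toward the smallest cut value.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = (labels[order] == labels.max()).astype(np.int64) if labels.size else labels
    n = v.size
    boundaries = np.nonzero(np.diff(v))[0]  # i where v[i] < v[i+1]
    if boundaries.size == 0:
        return None
    cum_pos = np.cumsum(y)
    total_pos = cum_pos[-1]
    n_left = boundaries + 1
    pos_left = cum_pos[boundaries]
    n_right = n - n_left
    pos_right = total_pos - pos_left
    base_ent = float(_binary_entropy(np.array([total_pos]), np.array([n]))[0])
    cond = (n_left / n) * _binary_entropy(pos_left, n_left) + (
        n_right / n
    ) * _binary_entropy(pos_right, n_right)
    gains = base_ent - cond
    best = float(np.max(gains))
    first = int(np.argmax(gains > best - 1e-12))  # smallest-cut tie-break
    i = boundaries[first]
    return float((v[i] + v[i + 1]) / 2.0), float(gains[first])


def mdlp_cut_points(values: Sequence[float], labels: Sequence[int]) -> list[float]:
    """Fit MDL-accepted cut points for one continuous feature.

    ``values`` and ``labels`` must be equal-length and free of missing values
    (missing values are excluded by the caller before entry).  Returns the
    sorted list of accepted cuts; possibly empty.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError(f"values and labels must be equal-length 1-D, got {v.shape} vs {y.shape}")
    if v.size == 0:
        raise ValueError("need at least one non-missing value")

    cuts: list[float] = []

    def recurse(vv: np.ndarray, yy: np.ndarray) -> None:
        if vv.size < 2 or _n_classes(yy) < 2:
            return
        found = _best_cut(vv, yy)
        if found is None:
            return
        cut, gain = found
        mask = vv <= cut
        left_y, right_y = yy[mask], yy[~mask]
        if not _accept_split(yy, left_y, right_y, gain):
            return
        cuts.append(float(cut))
        recurse(vv[mask], left_y)
        recurse(vv[~mask], right_y)

    recurse(v, y)
    return sorted(cuts)


@dataclass
class DiscretizationMap:
    """Per-feature ordered cut points and the interval items they induce."""

    cut_points: dict[str, list[float]] = field(default_factory=dict)

    def items_for(self, feature: str) -> list[FeatureValueItem]:
        """The k+1 interval items covering the real line for one feature."""
        cuts = self.cut_points[feature]
        edges = [-math.inf, *cuts, math.inf]
        return [
            FeatureValueItem(
                feature_name=feature,
                condition_kind="interval",
                interval_low=edges[i],
                interval_high=edges[i + 1],
                low_inclusive=False,
                high_inclusive=edges[i + 1] != math.inf,
            )
            for i in range(len(edges) - 1)
        ]

    def bin_index(self, feature: str, value: float) -> int:
        """0-based bin of a raw value; a value equal to a cut goes to the lower bin."""
        cuts = self.cut_points[feature]
        return int(np.searchsorted(np.asarray(cuts), value, side="left"))

    def bin_label(self, feature: str, value: float) -> str:
        return self.items_for(feature)[self.bin_index(feature, value)].item_key

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.cut_points, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "DiscretizationMap":
        with open(path) as fh:
            raw = json.load(fh)
        cuts = {}
        for feature, values in raw.items():
            values = [float(x) for x in values]
            if any(b <= a for a, b in zip(values, values[1:])):
                raise ValueError(f"cut points for {feature!r} must be strictly increasing")
            cuts[feature] = values
        return cls(cut_points=cuts)


def fit_discretization(
    table: pd.DataFrame,
    outcome: Sequence[int],
    features: Sequence[str] | None = None,
) -> DiscretizationMap:
    """Fit MDLP cuts for every numeric feature column (or the given subset).

    Rows with a missing feature value are excluded from that feature's fit.
    """
    y = np.asarray(outcome)
    if features is None:
        features = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    cuts = {}
    for feature in features:
        col = pd.to_numeric(table[feature], errors="raise")
        mask = col.notna().to_numpy()
        if not mask.any():
            cuts[feature] = []
            continue
        cuts[feature] = mdlp_cut_points(col.to_numpy(dtype=float)[mask], y[mask])
    return DiscretizationMap(cut_points=cuts)


def apply_discretization(table: pd.DataFrame, dmap: DiscretizationMap) -> pd.DataFrame:
    """Replace each mapped continuous column by its interval-item labels.

    Unmapped columns pass through unchanged (they become equals-items during
    mining); missing values stay missing.
    """
    out = table.copy()
    for feature, cuts in dmap.cut_points.items():
        if feature not in out.columns:
            raise KeyError(f"discretization map covers unknown feature {feature!r}")
        labels = [it.item_key for it in dmap.items_for(feature)]
        col = pd.to_numeric(out[feature], errors="raise")
        binned = pd.Series(
            np.searchsorted(np.asarray(cuts), col.to_numpy(dtype=float), side="left"),
            index=out.index,
        )
        result = binned.map(lambda i: labels[i])
        result[col.isna()] = None
        out[feature] = result
    return out
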