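"""Feature selection by random-forest mean-decrease-impurity importance.

Each feature receives the total Gini-impurity reduction attributable
to splits on it, averaged over the forest's trees and normalized so
scores sum to one. The top-k features by score feed either the 2D
feature mapping (k = 784 → 28×28) or the classical ML baselines
(k = 50). Selection is fit on the development (training+validation)
cohort only, never on held-out test patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .feature_table import FeatureTable, LabelVector, parse_feature_name
from .split import CohortSplit

__all__ = [
    "ImportanceRanking",
    "SelectedFeatures",
    "rf_importance",
    "select_top_k",
    "group_composition",
]

DEFAULT_N_TREES = 500  # stable MDI scores need a large forest


@dataclass
class ImportanceRanking:
    """Normalized per-feature importance scores with a total order.

    ``order[r]`` is the index (into ``feature_names``) of the rank-r
    feature; ties in score break by ascending feature name so the
    ranking is reproducible across platforms.
    """

    feature_names: list[str]
    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        p = len(self.feature_names)
        if self.scores.shape != (p,) or self.order.shape != (p,):
            raise ValueError("scores/order must match feature_names length")
        if (self.scores < 0).any():
            raise ValueError("importance scores must be ≥ 0")
        if not np.isclose(self.scores.sum(), 1.0, atol=1e-9):
            raise ValueError("importance scores must sum to 1")
        if sorted(self.order.tolist()) != list(range(p)):
            raise ValueError("order must be a permutation")

    def ranked_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.order]

    def rank_of(self, name: str) -> int:
        idx = self.feature_names.index(name)
        return int(np.nonzero(self.order == idx)[0][0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_name": self.ranked_names(),
                "score": self.scores[self.order],
                "rank": np.arange(len(self.feature_names)),
            }
        )

    @classmethod
    def from_scores(cls, feature_names: Sequence[str], scores: np.ndarray) -> "ImportanceRanking":
        scores = np.asarray(scores, dtype=float)
        total = scores.sum()
        if total <= 0:
            # a forest that never split (degenerate data): fall back to
            # the uniform ranking rather than dividing by zero
            scores = np.full(len(feature_names), 1.0 / len(feature_names))
        else:
            scores = scores / total
        # sort by (-score, name): descending score, name breaks ties
        order = sorted(range(len(feature_names)),
                       key=lambda i: (-scores[i], feature_names[i]))
        return cls(list(feature_names), scores, np.asarray(order))


@dataclass(frozen=True)
class SelectedFeatures:
    """Top-k feature names, rank 0 = highest importance."""

    names: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.names)


def rf_importance(
    table: FeatureTable,
    labels: LabelVector,
    *,
    split: CohortSplit | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ImportanceRanking:
    """Mean-decrease-impurity importance scores from a random forest.

    When ``split`` is given, only its development rows are used — the
    held-out test cohort must not influence which features survive.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be ≥ 1")
    if table.patient_ids != labels.patient_ids:
        raise ValueError("table and labels must be aligned (same ids, same order)")
    if split is not None:
        table = table.subset_patients(list(split.dev_ids))
        labels = labels.subset(list(split.dev_ids))
    classes = np.unique(labels.labels)
    if classes.size < 2:
        raise ValueError("both classes must be present to score features")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(table.values, labels.labels)
    return ImportanceRanking.from_scores(table.feature_names, forest.feature_importances_)


def select_top_k(ranking: ImportanceRanking, k: int) -> SelectedFeatures:
    """First k names in ranking order (k = 784 for the 28×28 mapping,
    k = 50 for the ML baselines)."""
    p = len(ranking.feature_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    return SelectedFeatures(tuple(ranking.ranked_names()[:k]))


def group_composition(selected: SelectedFeatures) -> pd.DataFrame:
    """Count selected features per group and per channel.

    Returns a tidy frame with columns (kind, category, count, percent);
    counts partition k and percentages sum to 100 within each kind.
    """
    groups: dict[str, int] = {}
    channels: dict[str, int] = {}
    for name in selected.names:
        d = parse_feature_name(name)
        groups[d.group] = groups.get(d.group, 0) + 1
        channels[d.channel] = channels.get(d.channel, 0) + 1
    k = selected.k
    rows = [
        {"kind": "group", "category": g, "count": c, "percent": 100.0 * c / k}
        for g, c in sorted(groups.items())
    ] + [
        {"kind": "channel", "category": ch, "count": c, "percent": 100.0 * c / k}
        for ch, c in sorted(channels.items())
    ]
    return pd.DataFrame(rows)
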