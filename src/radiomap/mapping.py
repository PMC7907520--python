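"""Feature mapping: z-score normalization and the center-out spiral.

The selected features are standardized (per-feature mean/SD estimated
on the training split, never on test data) and arranged into a square
matrix — the "feature mapping" that the CNN consumes as a one-channel
image. The arrangement places the most important feature at the
center and walks outward counterclockwise, so importance decays from
center to edge.

Spiral convention (documented, invertible, persisted with models):

* 0-based start cell ``(side//2 − 1, side//2 − 1)`` for even side,
  ``((side−1)//2, (side−1)//2)`` for odd side;
* first step moves right (col+1); turns are counterclockwise in image
  coordinates (right → up → left → down) with run lengths
  1, 1, 2, 2, 3, 3, …;
* cells falling outside the grid (unavoidable for even sides near the
  border) are skipped; the walk continues until side² cells are
  emitted. Skipping preserves ring monotonicity: the Chebyshev
  distance from the start cell never decreases with rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .selection import SelectedFeatures

__all__ = [
    "Normalizer",
    "SpiralLayout",
    "MappingSet",
    "fit_normalizer",
    "spiral_layout",
    "build_mappings",
    "unmap",
]


@dataclass
class Normalizer:
    """Per-feature z-scoring with training-split statistics."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        p = len(self.feature_names)
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise ValueError("means/sds must match feature_names length")
        if (self.sds <= 0).any():
            raise ValueError("zero-variance feature: cannot normalize")

    def transform(self, table: FeatureTable) -> np.ndarray:
        """Z-score the table's columns (restricted/reordered to the
        normalizer's features). Returns an (n, p) array."""
        sub = table.subset_features(self.feature_names)
        return (sub.values - self.means) / self.sds

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_name": self.feature_names, "mean": self.means, "sd": self.sds}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Normalizer":
        return cls(df["feature_name"].tolist(), df["mean"].to_numpy(), df["sd"].to_numpy())


def fit_normalizer(table: FeatureTable, train_ids: Sequence[str]) -> Normalizer:
    """Estimate per-feature mean and SD on the training rows only.

    Raises on zero-variance features: a constant feature carries no
    signal and would blow up the z-score.
    """
    if len(train_ids) == 0:
        raise ValueError("empty training split")
    sub = table.subset_patients(list(train_ids))
    means = sub.values.mean(axis=0)
    sds = sub.values.std(axis=0, ddof=0)
    if (sds <= 1e-12).any():
        bad = [n for n, s in zip(sub.feature_names, sds) if s <= 1e-12]
        raise ValueError(f"zero-variance features on the training split: {bad[:5]}")
    return Normalizer(sub.feature_names, means, sds)


def _spiral_walk(start: tuple[int, int]) -> Iterator[tuple[int, int]]:
    """Infinite counterclockwise square spiral from ``start``.

    Image coordinates: row grows downward. Direction cycle
    right → up → left → down with run lengths 1,1,2,2,3,3,…
    """
    directions = ((0, 1), (-1, 0), (0, -1), (1, 0))  # right, up, left, down
    r, c = start
    yield r, c
    run, d = 1, 0
    while True:
        for _ in range(2):
            dr, dc = directions[d]
            for _ in range(run):
                r, c = r + dr, c + dc
                yield r, c
            d = (d + 1) % 4
        run += 1


@dataclass
class SpiralLayout:
    """Bijection rank ↔ (row, col) on a side×side grid."""

    side: int
    rank_to_cell: np.ndarray  # (side², 2) int array

    def __post_init__(self) -> None:
        self.rank_to_cell = np.asarray(self.rank_to_cell, dtype=int)
        n = self.side * self.side
        if self.rank_to_cell.shape != (n, 2):
            raise ValueError("rank_to_cell must be (side², 2)")
        cells = {tuple(rc) for rc in self.rank_to_cell}
        if len(cells) != n or any(
            not (0 <= r < self.side and 0 <= c < self.side) for r, c in cells
        ):
            raise ValueError("rank_to_cell must be a bijection onto the grid")

    @property
    def start_cell(self) -> tuple[int, int]:
        return tuple(self.rank_to_cell[0])

    def cell_to_rank(self) -> np.ndarray:
        """Inverse map as a (side, side) array of ranks."""
        inv = np.empty((self.side, self.side), dtype=int)
        rows, cols = self.rank_to_cell[:, 0], self.rank_to_cell[:, 1]
        inv[rows, cols] = np.arange(self.side * self.side)
        return inv

    def to_dataframe(self, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
        n = self.side * self.side
        df = pd.DataFrame(
            {
                "rank": np.arange(n),
                "row": self.rank_to_cell[:, 0],
                "col": self.rank_to_cell[:, 1],
            }
        )
        if feature_names is not None:
            df["feature_name"] = list(feature_names)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpiralLayout":
        df = df.sort_values("rank")
        side = int(np.sqrt(len(df)))
        return cls(side, df[["row", "col"]].to_numpy())


def spiral_layout(side: int) -> SpiralLayout:
    """Build the documented center-out counterclockwise layout."""
    if side < 1:
        raise ValueError("side must be ≥ 1")
    start = (side // 2 - 1, side // 2 - 1) if side % 2 == 0 else ((side - 1) // 2,) * 2
    n = side * side
    cells = []
    for r, c in _spiral_walk(start):
        if 0 <= r < side and 0 <= c < side:
            cells.append((r, c))
            if len(cells) == n:
                break
    return SpiralLayout(side, np.asarray(cells))


@dataclass
class MappingSet:
    """Per-patient feature mappings: one side×side matrix each.

    ``values[i][layout.rank_to_cell[r]]`` is the normalized value of
    patient i's rank-r feature; ``feature_names[r]`` names it.
    """

    patient_ids: list[str]
    values: np.ndarray  # (n, side, side)
    layout: SpiralLayout
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.patient_ids)
        s = self.layout.side
        if self.values.shape != (n, s, s):
            raise ValueError(f"values must be (n, {s}, {s})")
        if len(self.feature_names) != s * s:
            raise ValueError("feature_names must have side² entries")

    @property
    def side(self) -> int:
        return self.layout.side

    def feature_at(self, row: int, col: int) -> str:
        """Inverse lookup: which feature sits in a given cell."""
        rank = int(self.layout.cell_to_rank()[row, col])
        return self.feature_names[rank]

    def subset(self, ids: Sequence[str]) -> "MappingSet":
        index = {pid: i for i, pid in enumerate(self.patient_ids)}
        rows = [index[pid] for pid in ids]
        return MappingSet(list(ids), self.values[rows], self.layout, self.feature_names)


def build_mappings(
    table: FeatureTable,
    selected: SelectedFeatures,
    normalizer: Normalizer,
    layout: SpiralLayout,
) -> MappingSet:
    """Normalize the selected features and scatter them onto the grid."""
    if layout.side * layout.side != selected.k:
        raise ValueError(
            f"layout side² = {layout.side ** 2} must equal k = {selected.k}"
        )
    if list(normalizer.feature_names) != list(selected.names):
        raise ValueError("normalizer must be fit on the selected features, in rank order")
    z = normalizer.transform(table)  # (n, k) in rank order
    n, s = z.shape[0], layout.side
    values = np.empty((n, s, s), dtype=float)
    rows, cols = layout.rank_to_cell[:, 0], layout.rank_to_cell[:, 1]
    values[:, rows, cols] = z
    return MappingSet(list(table.patient_ids), values, layout, list(selected.names))


def unmap(mappings: MappingSet) -> np.ndarray:
    """Recover the (n, k) normalized feature matrix in rank order."""
    rows, cols = mappings.layout.rank_to_cell[:, 0], mappings.layout.rank_to_cell[:, 1]
    return mappings.values[:, rows, cols]
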