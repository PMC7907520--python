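"""Cohort splitting.

The cohort design: a development cohort (internally split into
training and validation, stratified by label) and one or more held-out
test cohorts. Feature selection and normalization statistics are fit
on the development split only — the split object is threaded through
the API so downstream stages cannot silently touch test rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .feature_table import LabelVector

__all__ = ["CohortSplit", "TrainValSplit", "stratified_split", "train_val_split"]


@dataclass(frozen=True)
class CohortSplit:
    """Development vs. held-out test patient ids."""

    dev_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.dev_ids:
            raise ValueError("empty development split")
        if set(self.dev_ids) & set(self.test_ids):
            raise ValueError("development and test splits overlap")


@dataclass(frozen=True)
class TrainValSplit:
    """Training vs. validation ids within the development cohort."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.train_ids or not self.val_ids:
            raise ValueError("train and validation splits must be nonempty")
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train and validation splits overlap")


def stratified_split(labels: LabelVector, test_size: int | float, seed: int) -> CohortSplit:
    """Stratified development/test split (e.g. 638 dev / 71 test)."""
    dev, test = train_test_split(
        np.asarray(labels.patient_ids, dtype=object),
        test_size=test_size,
        stratify=labels.labels,
        random_state=seed,
    )
    return CohortSplit(tuple(dev), tuple(test))


def train_val_split(labels: LabelVector, val_fraction: float, seed: int) -> TrainValSplit:
    """Stratified train/validation split of a development cohort."""
    train, val = train_test_split(
        np.asarray(labels.patient_ids, dtype=object),
        test_size=val_fraction,
        stratify=labels.labels,
        random_state=seed,
    )
    return TrainValSplit(tuple(train), tuple(val))
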