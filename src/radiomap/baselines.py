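"""Classical ML comparators: SVM, random forest, and MLP.

Five reference models frame the deep classifier: three on the top-50
radiomics features (SVM, RF, MLP), one on clinical covariates only
(SVM), and one combined (SVM on radiomics + clinical). Hyperparameters
are fixed: SVM with an RBF kernel, C=3, γ=1;
RF with 4 estimators; MLP with hidden layers (10, 5), ReLU, Adam.

SVM scores are the signed decision function — rank-equivalent to a
probability for ROC/AUC purposes, with the hard-label cut at 0; RF and
MLP emit class-1 probabilities cut at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .feature_table import SUBTYPES, ClinicalRecord

__all__ = ["BaselineSpec", "ClinicalEncoder", "FittedBaseline", "fit_baseline", "DEFAULT_HYPERPARAMETERS"]

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "svm": {"C": 3.0, "gamma": 1.0, "kernel": "rbf"},
    "rf": {"n_estimators": 4},
    "mlp": {"hidden_layer_sizes": (10, 5), "activation": "relu", "solver": "adam"},
}


@dataclass(frozen=True)
class BaselineSpec:
    """Which classifier on which feature set, with hyperparameters."""

    classifier: str  # svm | rf | mlp
    feature_set: str  # radiomics | clinical | combined
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.feature_set not in ("radiomics", "clinical", "combined"):
            raise ValueError(f"unknown feature set {self.feature_set!r}")

    def resolved_hyperparameters(self) -> dict:
        out = dict(DEFAULT_HYPERPARAMETERS[self.classifier])
        out.update(self.hyperparameters)
        return out


class ClinicalEncoder:
    """Encode clinical records to a numeric matrix.

    Columns: gender (male=1, female=0), age z-scored with statistics
    from the records the encoder was fit on, then one-hot over the
    eight histopathological subtypes (all-zero when the cohort lacks
    subtype annotation, as external cohorts may).
    """

    def __init__(self) -> None:
        self.age_mean: float | None = None
        self.age_sd: float | None = None

    @property
    def columns(self) -> list[str]:
        return ["gender_male", "age_z"] + [f"subtype_{s}" for s in SUBTYPES]

    def fit(self, records: Sequence[ClinicalRecord]) -> "ClinicalEncoder":
        if not records:
            raise ValueError("cannot fit encoder on an empty cohort")
        ages = np.array([r.age for r in records], dtype=float)
        self.age_mean = float(ages.mean())
        self.age_sd = float(ages.std(ddof=0)) or 1.0
        return self

    def transform(self, records: Sequence[ClinicalRecord]) -> np.ndarray:
        if self.age_mean is None:
            raise ValueError("encoder must be fit before transform")
        rows = np.zeros((len(records), 2 + len(SUBTYPES)))
        for i, r in enumerate(records):
            rows[i, 0] = 1.0 if r.gender == "male" else 0.0
            rows[i, 1] = (r.age - self.age_mean) / self.age_sd
            if r.subtype is not None:
                rows[i, 2 + SUBTYPES.index(r.subtype)] = 1.0
        return rows

    def fit_transform(self, records: Sequence[ClinicalRecord]) -> np.ndarray:
        return self.fit(records).transform(records)


def encode_clinical(records: Sequence[ClinicalRecord],
                    encoder: ClinicalEncoder | None = None) -> np.ndarray:
    """One-shot encoding (fits on the given records when no encoder is
    supplied; pass a train-fitted encoder for test cohorts)."""
    if encoder is None:
        return ClinicalEncoder().fit_transform(records)
    return encoder.transform(records)


@dataclass
class FittedBaseline:
    """A trained comparator exposing ROC-ready scores (higher = more
    likely mutated)."""

    spec: BaselineSpec
    estimator: object
    threshold: float

    def scores(self, features: np.ndarray) -> np.ndarray:
        if isinstance(self.estimator, SVC):
            return self.estimator.decision_function(features)
        return self.estimator.predict_proba(features)[:, 1]


def fit_baseline(
    spec: BaselineSpec, features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> FittedBaseline:
    """Train one comparator with its fixed hyperparameters."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must align")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to fit a classifier")
    hp = spec.resolved_hyperparameters()
    if spec.classifier == "svm":
        est = SVC(**hp)
        threshold = 0.0  # decision-function cut
    elif spec.classifier == "rf":
        est = RandomForestClassifier(random_state=seed, **hp)
        threshold = 0.5
    else:
        est = MLPClassifier(random_state=seed, max_iter=1000, **hp)
        threshold = 0.5
    est.fit(features, labels)
    return FittedBaseline(spec=spec, estimator=est, threshold=threshold)
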