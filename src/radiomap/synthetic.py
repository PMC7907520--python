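"""Synthetic cohort generator.

Real CT cohorts with genotyped lesions are private; this module
produces statistically analogous stand-ins so the whole pipeline
(selection → mapping → CNN → evaluation) is testable end to end. A
cohort is a Gaussian feature table in which

* a minority of *informative* features carries a class-conditional
  mean shift of ``effect_size`` pooled standard deviations (the
  standardized effect d), emulating the handful of discriminative
  radiomics features among ~1,000 extracted ones;
* features are grouped into equicorrelated blocks (pairwise
  correlation ``block_rho`` within a block), emulating the strong
  redundancy of radiomics features derived from shared image
  statistics;
* every feature has unit marginal variance, so normalization is
  exercised but not load-bearing.

Informative features are spread evenly across the catalog so that
group/channel composition reporting downstream sees a mixed plant.
Clinical covariates are generated alongside: age ~ N(60, 10²) years
(uninformative), gender with a configurable association to the label
(default none), and a random histopathological subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_table import (
    SUBTYPES,
    ClinicalRecord,
    FeatureTable,
    LabelVector,
    enumerate_catalog,
)

__all__ = ["SimConfig", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Cohort generation parameters.

    Defaults match the intended cohort scale: ~700 patients, ~1,000
    features of which a few dozen are discriminative, balanced classes.
    """

    n_patients: int = 700
    n_features: int = 1000
    n_informative: int = 30
    effect_size: float = 1.5
    block_size: int = 10
    block_rho: float = 0.3
    class_balance: float = 0.5
    gender_assoc: float = 0.0
    include_subtype: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_features < 1:
            raise ValueError("n_patients and n_features must be ≥ 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 ≤ n_informative ≤ n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be ≥ 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be ≥ 1")
        if not -0.5 <= self.gender_assoc <= 0.5:
            raise ValueError("gender_assoc must lie in [-0.5, 0.5]")


def informative_indices(config: SimConfig) -> np.ndarray:
    """Deterministic informative-feature positions, spread evenly
    across the feature list (hence across catalog groups/channels)."""
    if config.n_informative == 0:
        return np.empty(0, dtype=int)
    return np.unique(
        np.linspace(0, config.n_features - 1, config.n_informative).round().astype(int)
    )


def simulate_cohort(config: SimConfig):
    """Generate ``(FeatureTable, LabelVector, list[ClinicalRecord])``.

    Fully reproducible from ``config.seed``: equal configs produce
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_features

    labels = (rng.random(n) < config.class_balance).astype(int)

    # Equicorrelated blocks with unit marginal variance:
    # x = sqrt(rho)·shared_block + sqrt(1−rho)·idiosyncratic.
    eps = rng.standard_normal((n, p))
    n_blocks = -(-p // config.block_size)
    shared = rng.standard_normal((n, n_blocks))
    block_of = np.arange(p) // config.block_size
    x = np.sqrt(config.block_rho) * shared[:, block_of] + np.sqrt(1.0 - config.block_rho) * eps

    info = informative_indices(config)
    if info.size:
        shift = np.where(labels == 1, config.effect_size / 2.0, -config.effect_size / 2.0)
        x[:, info] += shift[:, None]

    catalog = enumerate_catalog()
    if p > len(catalog):
        raise ValueError(
            f"n_features={p} exceeds the default catalog size {len(catalog)}"
        )
    features = catalog[:p]
    ids = [f"P{i:04d}" for i in range(n)]
    table = FeatureTable(ids, features, x)
    label_vec = LabelVector(list(ids), labels)

    # Clinical covariates. gender_assoc shifts P(male | EGFR(+)) away
    # from 0.5; at the default 0.0 gender carries no label information.
    ages = np.clip(rng.normal(60.0, 10.0, n), 18.0, 95.0)
    p_male = 0.5 + config.gender_assoc * (2 * labels - 1)
    male = rng.random(n) < p_male
    subtype_idx = rng.integers(0, len(SUBTYPES), n)
    records = [
        ClinicalRecord(
            patient_id=ids[i],
            age=float(round(ages[i], 1)),
            gender="male" if male[i] else "female",
            subtype=SUBTYPES[subtype_idx[i]] if config.include_subtype else None,
        )
        for i in range(n)
    ]
    return table, label_vec, records
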