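"""End-to-end workflow: simulate/load → split → select → map → train →
evaluate, with persisted, manifest-tracked artifacts.

Every stage is seeded explicitly; a rerun with an identical
configuration reproduces identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import baselines as bl
from . import evaluation as ev
from . import secnn
from .feature_table import (
    align,
    read_clinical,
    read_feature_table,
    read_labels,
    write_clinical,
    write_feature_table,
    write_labels,
)
from .mapping import build_mappings, fit_normalizer, spiral_layout
from .selection import rf_importance, select_top_k
from .split import stratified_split, train_val_split
from .synthetic import SimConfig, simulate_cohort

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (detected before any compute)."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "run"
    # inputs: either a synthetic cohort or CSV paths
    simulate: SimConfig | None = None
    features_csv: str | None = None
    labels_csv: str | None = None
    clinical_csv: str | None = None
    # selection / mapping
    k: int = 784
    k_baseline: int = 50
    n_trees: int = 500
    selection_seed: int = 0
    side: int = 28
    # models
    models: tuple[str, ...] = ("secnn",)
    conv: secnn.ConvStackConfig = field(default_factory=secnn.ConvStackConfig)
    train: secnn.TrainConfig = field(default_factory=secnn.TrainConfig)
    run_baselines: bool = False
    # split
    test_size: float = 0.1
    val_fraction: float = 0.2
    split_seed: int = 0

    def validate(self) -> None:
        if self.side * self.side != self.k:
            raise ConfigError(f"side² = {self.side ** 2} must equal k = {self.k}")
        if self.simulate is None and (self.features_csv is None or self.labels_csv is None):
            raise ConfigError("either a simulate block or feature+label CSV paths are required")
        for kind in self.models:
            if kind not in ("secnn", "cnn", "cnn1d"):
                raise ConfigError(f"unknown model kind {kind!r}")
        if self.conv.input_side != self.side:
            raise ConfigError("conv.input_side must equal the mapping side")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimConfig(**raw["simulate"])
        if "conv" in raw:
            conv = dict(raw["conv"])
            if "filters" in conv:
                conv["filters"] = tuple(conv["filters"])
            raw["conv"] = secnn.ConvStackConfig(**conv)
        if "train" in raw:
            raw["train"] = secnn.TrainConfig(**raw["train"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        if self.conv is not None:
            d["conv"]["filters"] = list(self.conv.filters)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # hash the computation, not its location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to
    ``out_dir/summary.json`` beside a manifest of every artifact)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        table, labels, clinical = simulate_cohort(config.simulate)
        save("features.csv", lambda p: write_feature_table(table, p))
        save("labels.csv", lambda p: write_labels(labels, p))
        save("clinical.csv", lambda p: write_clinical(clinical, p))
    else:
        table = read_feature_table(config.features_csv)
        labels = read_labels(config.labels_csv)
        clinical = read_clinical(config.clinical_csv) if config.clinical_csv else None
    if clinical is not None:
        table, labels, clinical = align(table, labels, clinical)
    else:
        table, labels = align(table, labels)

    # --- splits -----------------------------------------------------------
    cohort = stratified_split(labels, config.test_size, config.split_seed)
    dev_labels = labels.subset(list(cohort.dev_ids))
    tv = train_val_split(dev_labels, config.val_fraction, config.split_seed)

    # --- selection (development cohort only) ------------------------------
    ranking = rf_importance(
        table, labels, split=cohort, n_trees=config.n_trees, seed=config.selection_seed
    )
    save("ranking.csv", lambda p: ranking.to_dataframe().to_csv(p, index=False))
    selected = select_top_k(ranking, config.k)

    # --- mapping ----------------------------------------------------------
    sub = table.subset_features(list(selected.names))
    normalizer = fit_normalizer(sub, list(cohort.dev_ids))
    layout = spiral_layout(config.side)
    save("layout.csv", lambda p: layout.to_dataframe(selected.names).to_csv(p, index=False))
    save("normalizer.csv", lambda p: normalizer.to_dataframe().to_csv(p, index=False))
    mappings = build_mappings(table, selected, normalizer, layout)

    # --- deep models ------------------------------------------------------
    test_ids = list(cohort.test_ids)
    y_all = dict(zip(labels.patient_ids, labels.labels))
    y_test = np.array([y_all[pid] for pid in test_ids])
    dev_mappings = mappings.subset(list(cohort.dev_ids))
    y_dev = np.array([y_all[pid] for pid in cohort.dev_ids])
    reports: dict[str, dict] = {}
    for kind in config.models:
        conv = dataclasses.replace(config.conv, use_se=(kind == "secnn"))
        net = secnn.build_model(kind, conv, seed=config.train.seed)
        trained = secnn.train(net, dev_mappings, y_dev, tv, config.train, normalizer)
        ckpt = out / f"checkpoint_{kind}"
        secnn.save_checkpoint(trained, ckpt)
        scores = secnn.predict(trained, mappings.subset(test_ids))
        rep = ev.make_report(kind, "test", scores, y_test)
        save(f"report_{kind}.json", lambda p, rep=rep: rep.to_json(p))
        reports[kind] = rep.to_dict()

    # --- classical baselines ---------------------------------------------
    if config.run_baselines:
        sel50 = select_top_k(ranking, config.k_baseline)
        sub50 = table.subset_features(list(sel50.names))
        norm50 = fit_normalizer(sub50, list(cohort.dev_ids))
        z_dev = norm50.transform(sub50.subset_patients(list(cohort.dev_ids)))
        z_test = norm50.transform(sub50.subset_patients(test_ids))
        specs = [bl.BaselineSpec(c, "radiomics") for c in ("svm", "rf", "mlp")]
        enc = None
        if clinical is not None:
            by_id = {r.patient_id: r for r in clinical}
            dev_rec = [by_id[p] for p in cohort.dev_ids]
            test_rec = [by_id[p] for p in test_ids]
            enc = bl.ClinicalEncoder().fit(dev_rec)
            c_dev, c_test = enc.transform(dev_rec), enc.transform(test_rec)
            specs += [bl.BaselineSpec("svm", "clinical"), bl.BaselineSpec("svm", "combined")]
        for spec in specs:
            if spec.feature_set == "radiomics":
                x_dev, x_test = z_dev, z_test
            elif spec.feature_set == "clinical":
                x_dev, x_test = c_dev, c_test
            else:
                x_dev = np.hstack([z_dev, c_dev])
                x_test = np.hstack([z_test, c_test])
            fitted = bl.fit_baseline(spec, x_dev, y_dev, seed=config.split_seed)
            rep = ev.make_report(
                f"{spec.feature_set}_{spec.classifier}", "test",
                fitted.scores(x_test), y_test, threshold=fitted.threshold,
            )
            save(f"report_{rep.model_id}.json", lambda p, rep=rep: rep.to_json(p))
            reports[rep.model_id] = rep.to_dict()

    # --- summary + manifest ----------------------------------------------
    summary = {
        "config_hash": config.config_hash(),
        "n_patients": table.n_patients,
        "n_features": table.n_features,
        "n_dev": len(cohort.dev_ids),
        "n_test": len(test_ids),
        "k": config.k,
        "side": config.side,
        "reports": reports,
    }
    save("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2)))
    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
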