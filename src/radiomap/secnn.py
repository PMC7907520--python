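"""Squeeze-and-excitation CNN for feature-mapping classification.

The classifier consumes a patient's 28×28 feature mapping as a
one-channel image and emits a mutation probability. Architecture
(all sizes config-exposed):

    conv 3×3×f1 (same, ReLU) → SE(r) → 2×2 max pool →
    conv 3×3×f2 (same, ReLU) → SE(r) → 2×2 max pool →
    flatten → dropout → dense (ReLU) → dense 1 (sigmoid)

Two ablations share the stack: ``cnn`` drops the two SE blocks, and
``cnn1d`` applies the analogous 1D stack (two convolutions, one max
pool, one global average pool) to the rank-ordered feature vector.

The SE block computes, for input U with channels c = 1..C:

    squeeze   z_c = mean over the H×W plane of u_c
    excite    s   = sigmoid(W2 · relu(W1 · z)),  W1: (C/r)×C, W2: C×(C/r)
    scale     x̃_c = s_c · u_c

Training minimizes binary cross-entropy with Adam (batch 50,
learning rate 0.001) and stops early once the validation loss has
failed to improve for ``patience`` consecutive epochs, restoring the
best-validation parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import layers as L
from .mapping import MappingSet, Normalizer, SpiralLayout, unmap
from .split import TrainValSplit

__all__ = [
    "SEBlockParams", "ConvStackConfig", "TrainConfig", "TrainedModel",
    "squeeze", "excite", "se_scale", "se_block", "bce_loss", "bce_grad",
    "build_model", "train", "predict", "save_checkpoint", "load_checkpoint",
    "SequentialNet",
]

BCE_EPS = 1e-7  # probability clip before taking logs


# ---------------------------------------------------------------------------
# SE-block primitives (functional form, single tensor or batch)

@dataclass
class SEBlockParams:
    """Excitation weights for a C-channel block with reduction r."""

    channels: int
    reduction: int
    W1: np.ndarray  # (C/r, C)
    W2: np.ndarray  # (C, C/r)

    def __post_init__(self) -> None:
        c, r = self.channels, self.reduction
        if c % r:
            raise ValueError(f"channels {c} must be divisible by reduction {r}")
        if self.W1.shape != (c // r, c) or self.W2.shape != (c, c // r):
            raise ValueError("W1/W2 shapes inconsistent with (channels, reduction)")


def squeeze(u: np.ndarray) -> np.ndarray:
    """Global average pool: channel descriptor z_c = mean of plane c.

    Accepts (C, H, W) or a batch (N, C, H, W).
    """
    if u.ndim not in (3, 4) or u.size == 0:
        raise ValueError("expected a nonempty (C,H,W) or (N,C,H,W) tensor")
    return u.mean(axis=(-2, -1))


def excite(z: np.ndarray, params: SEBlockParams) -> np.ndarray:
    """Channel gates s = sigmoid(W2 · relu(W1 · z)); each s_c ∈ (0, 1)."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != params.channels:
        raise ValueError(f"z has {z.shape[-1]} channels, params expect {params.channels}")
    return L.sigmoid(L.relu(z @ params.W1.T) @ params.W2.T)


def se_scale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling x̃_c = s_c · u_c."""
    if u.shape[-3] != s.shape[-1]:
        raise ValueError("channel count of u and s differ")
    if u.ndim == 3:
        return u * s[:, None, None]
    return u * s[..., :, None, None]


def se_block(u: np.ndarray, params: SEBlockParams) -> np.ndarray:
    """Full squeeze → excite → scale composition."""
    return se_scale(u, excite(squeeze(u), params))


# ---------------------------------------------------------------------------
# Binary cross-entropy

def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), BCE_EPS, 1.0 - BCE_EPS)


def bce_loss(y_pred: np.ndarray, y_true: np.ndarray, reduction: str = "sum") -> float:
    """Binary cross-entropy −Σ[ŷ log y + (1−ŷ) log(1−y)] (natural log).

    ``reduction="mean"`` divides by n (used inside the training loop so
    the learning rate is batch-size independent).
    """
    y_pred = _clip(y_pred)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape:
        raise ValueError("y_pred and y_true must have the same length")
    terms = y_true * np.log(y_pred) + (1.0 - y_true) * np.log(1.0 - y_pred)
    return float(-terms.mean() if reduction == "mean" else -terms.sum())


def bce_grad(y_pred: np.ndarray, y_true: np.ndarray) -> np.ndarray:
    """Per-sample gradient of the summed loss w.r.t. the predicted
    probability: ∂loss/∂y_i = −(ŷ_i/y_i − (1−ŷ_i)/(1−y_i))."""
    y_pred = _clip(y_pred)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape:
        raise ValueError("y_pred and y_true must have the same length")
    return -(y_true / y_pred - (1.0 - y_true) / (1.0 - y_pred))


# ---------------------------------------------------------------------------
# Architecture / training configuration

@dataclass(frozen=True)
class ConvStackConfig:
    """Architecture hyperparameters. The stack is deliberately shallow
    (two convolutional layers): with fewer than a thousand training
    patients, deeper nets overfit the feature mappings."""

    n_conv_layers: int = 2
    filters: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    kernel_size_1d: int = 7
    pool: str = "max"
    pool_size: int = 2
    use_se: bool = True
    se_reduction: int = 8
    dropout_rate: float = 0.5
    dense_units: int = 64
    input_side: int = 28

    def __post_init__(self) -> None:
        if self.n_conv_layers != 2:
            raise ValueError("the stack is defined with exactly two convolutional layers")
        if len(self.filters) != 2:
            raise ValueError("need one filter count per convolutional layer")
        if self.use_se and any(f % self.se_reduction for f in self.filters):
            raise ValueError("filter counts must be divisible by the SE reduction ratio")
        if self.pool != "max":
            raise ValueError("only max pooling is supported in the 2D stack")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_side % (self.pool_size ** 2):
            raise ValueError("input_side must be divisible by pool_size² (two pools)")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 50
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 5
    max_epochs: int = 200
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be ≥ 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


class SequentialNet:
    """A feed-forward stack with a single sigmoid probability output."""

    def __init__(self, kind: str, config: ConvStackConfig, layer_list: list[L.Layer],
                 rng: np.random.Generator) -> None:
        self.kind = kind
        self.config = config
        self.layers = layer_list
        self.rng = rng

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lyr in self.layers for p in lyr.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lyr in self.layers for g in lyr.grads]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x[:, 0]  # (N,) probabilities

    def backward(self, dprob: np.ndarray) -> None:
        grad = dprob[:, None]
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)

    def se_blocks(self) -> list[L.SEBlock]:
        return [lyr for lyr in self.layers if isinstance(lyr, L.SEBlock)]

    def prepare_input(self, mappings: MappingSet | np.ndarray) -> np.ndarray:
        """Convert a mapping set to the network's input tensor."""
        if self.kind == "cnn1d":
            vec = unmap(mappings) if isinstance(mappings, MappingSet) else mappings
            return vec[:, None, :]
        arr = mappings.values if isinstance(mappings, MappingSet) else mappings
        if arr.ndim == 3:
            arr = arr[:, None, :, :]
        side = self.config.input_side
        if arr.shape[-2:] != (side, side):
            raise ValueError(f"mapping side {arr.shape[-2:]} != model input {side}")
        return arr


def build_model(kind: str, config: ConvStackConfig | None = None, seed: int = 0) -> SequentialNet:
    """Construct an untrained model: ``secnn``, ``cnn`` (no SE), or
    ``cnn1d``. Same seed ⇒ identical initial parameters."""
    config = config or ConvStackConfig(use_se=(kind == "secnn"))
    if kind == "secnn" and not config.use_se:
        config = dataclasses.replace(config, use_se=True)
    if kind == "cnn" and config.use_se:
        config = dataclasses.replace(config, use_se=False)
    rng = np.random.default_rng(seed)
    f1, f2 = config.filters
    r = config.se_reduction
    net: list[L.Layer] = []
    if kind in ("secnn", "cnn"):
        side = config.input_side
        net.append(L.Conv2D(1, f1, config.kernel_size, rng, activation="relu"))
        if config.use_se:
            net.append(L.SEBlock(f1, r, rng))
        net.append(L.MaxPool2D(config.pool_size))
        net.append(L.Conv2D(f1, f2, config.kernel_size, rng, activation="relu"))
        if config.use_se:
            net.append(L.SEBlock(f2, r, rng))
        net.append(L.MaxPool2D(config.pool_size))
        net.append(L.Flatten())
        net.append(L.Dropout(config.dropout_rate, rng))
        flat = f2 * (side // config.pool_size ** 2) ** 2
        net.append(L.Dense(flat, config.dense_units, rng, activation="relu"))
        net.append(L.Dense(config.dense_units, 1, rng, activation="sigmoid"))
    elif kind == "cnn1d":
        net.append(L.Conv1D(1, f1, config.kernel_size_1d, rng, activation="relu"))
        net.append(L.MaxPool1D(config.pool_size))
        net.append(L.Conv1D(f1, f2, config.kernel_size_1d, rng, activation="relu"))
        net.append(L.GlobalAvgPool1D())
        net.append(L.Dropout(config.dropout_rate, rng))
        net.append(L.Dense(f2, config.dense_units, rng, activation="relu"))
        net.append(L.Dense(config.dense_units, 1, rng, activation="sigmoid"))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return SequentialNet(kind, config, net, rng)


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reproduce and apply it."""

    net: SequentialNet
    train_config: TrainConfig
    history: pd.DataFrame  # epoch, train_loss, train_acc, val_loss, val_acc
    stopped_epoch: int
    normalizer: Normalizer | None = None
    layout: SpiralLayout | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.history) != self.stopped_epoch:
            raise ValueError("history length must equal stopped_epoch")
        if self.layout is not None and self.net.kind != "cnn1d":
            if self.layout.side != self.net.config.input_side:
                raise ValueError("stored layout side differs from the architecture input side")


def train(
    model: SequentialNet,
    mappings: MappingSet,
    labels: np.ndarray,
    split: TrainValSplit,
    tc: TrainConfig,
    normalizer: Normalizer | None = None,
) -> TrainedModel:
    """Mini-batch Adam with early stopping on validation loss.

    Stops at the first epoch after ``patience`` consecutive epochs
    without strict validation-loss improvement, or at ``max_epochs``;
    the best-validation parameters are restored. Fully reproducible
    given (data, split, seed).
    """
    ids = list(mappings.patient_ids)
    labels = np.asarray(labels)
    if len(labels) != len(ids):
        raise ValueError("labels must align with mappings")
    by_id = {pid: i for i, pid in enumerate(ids)}
    tr = [by_id[pid] for pid in split.train_ids]
    va = [by_id[pid] for pid in split.val_ids]
    y_tr, y_va = labels[tr], labels[va]
    if np.unique(y_tr).size < 2:
        raise ValueError("training labels contain a single class")

    x_all = model.prepare_input(mappings)
    x_tr, x_va = x_all[tr], x_all[va]

    rng = np.random.default_rng(tc.seed)
    model.rng = rng  # drives per-batch dropout masks
    opt = L.Adam(model.params, model.grads, lr=tc.learning_rate)

    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    bad_epochs = 0
    rows = []
    n_tr = len(tr)
    for epoch in range(1, tc.max_epochs + 1):
        perm = rng.permutation(n_tr)
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, n_tr, tc.batch_size):
            idx = perm[start:start + tc.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            p = model.forward(xb, train=True)
            ep_loss += bce_loss(p, yb, reduction="sum")
            ep_correct += int(((p >= 0.5).astype(int) == yb).sum())
            model.backward(bce_grad(p, yb) / len(idx))
            opt.step()
        p_va = model.forward(x_va, train=False)
        val_loss = bce_loss(p_va, y_va, reduction="mean")
        rows.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / n_tr,
                "train_acc": ep_correct / n_tr,
                "val_loss": val_loss,
                "val_acc": float(((p_va >= 0.5).astype(int) == y_va).mean()),
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tc.patience:
                break
    model.set_weights(best_weights)
    history = pd.DataFrame(rows)
    return TrainedModel(
        net=model,
        train_config=tc,
        history=history,
        stopped_epoch=int(history["epoch"].iloc[-1]),
        normalizer=normalizer,
        layout=mappings.layout,
        feature_names=list(mappings.feature_names),
    )


def predict(trained: TrainedModel, mappings: MappingSet | np.ndarray) -> np.ndarray:
    """Per-patient mutation probability, deterministic (inference mode)."""
    x = trained.net.prepare_input(mappings)
    return trained.net.forward(x, train=False)


# ---------------------------------------------------------------------------
# Checkpointing: YAML config + npz parameters + CSV sidecars

def save_checkpoint(trained: TrainedModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": trained.net.kind,
        "architecture": dataclasses.asdict(trained.net.config),
        "train_config": dataclasses.asdict(trained.train_config),
        "stopped_epoch": trained.stopped_epoch,
    }
    (d / "config.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    np.savez(d / "params.npz", **{f"p{i}": p for i, p in enumerate(trained.net.params)})
    trained.history.to_csv(d / "history.csv", index=False)
    if trained.layout is not None:
        trained.layout.to_dataframe(trained.feature_names).to_csv(d / "layout.csv", index=False)
    if trained.normalizer is not None:
        trained.normalizer.to_dataframe().to_csv(d / "normalizer.csv", index=False)


def load_checkpoint(directory) -> TrainedModel:
    d = Path(directory)
    meta = yaml.safe_load((d / "config.yaml").read_text())
    arch = meta["architecture"]
    arch["filters"] = tuple(arch["filters"])
    config = ConvStackConfig(**arch)
    net = build_model(meta["kind"], config, seed=0)
    with np.load(d / "params.npz") as npz:
        net.set_weights([npz[f"p{i}"] for i in range(len(npz.files))])
    history = pd.read_csv(d / "history.csv")
    layout = feature_names = normalizer = None
    if (d / "layout.csv").exists():
        ldf = pd.read_csv(d / "layout.csv")
        layout = SpiralLayout.from_dataframe(ldf)
        if "feature_name" in ldf.columns:
            feature_names = ldf.sort_values("rank")["feature_name"].tolist()
    if (d / "normalizer.csv").exists():
        normalizer = Normalizer.from_dataframe(pd.read_csv(d / "normalizer.csv"))
    return TrainedModel(
        net=net,
        train_config=TrainConfig(**meta["train_config"]),
        history=history,
        stopped_epoch=int(meta["stopped_epoch"]),
        normalizer=normalizer,
        layout=layout,
        feature_names=feature_names,
    )
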