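"""Training loop: Adam optimization, early stopping, per-epoch metric history.

The default protocol follows the architecture's training configuration: Adam
at learning rate 0.001, categorical cross-entropy as the optimized objective,
early stopping on validation loss with patience 5 and best-weight restoration.
Tversky and boundary losses are tracked as monitored metrics every epoch; an
optional composite mode optimizes
``CE + lambda_tversky * Tversky + lambda_boundary * Boundary`` instead.

"Improvement" means a strict decrease of the monitored quantity by more than
``min_delta`` (default 0); ties count toward patience.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .exceptions import ConfigurationError, DataError
from .losses_metrics import (BoundaryParams, TverskyParams, boundary_loss,
                             confusion_counts, cross_entropy_graph, one_hot,
                             precision_accuracy_dice, sensitivity, specificity,
                             tversky_loss, tversky_loss_graph,
                             boundary_loss_graph)
from .model import GNet

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainingHistory", "EarlyStopping", "train",
           "train_steps"]


@dataclass
class TrainConfig:
    """Optimization protocol configuration."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    max_epochs: int = 50
    early_stopping: bool = True
    early_stopping_patience: int = 5
    min_delta: float = 0.0
    monitor: str = "val_loss"
    batch_size: int = 8
    seed: int = 0
    loss_mode: str = "ce"            # "ce" or "composite"
    lambda_tversky: float = 1.0
    lambda_boundary: float = 1.0
    tversky: TverskyParams = field(default_factory=TverskyParams)
    boundary: BoundaryParams = field(default_factory=BoundaryParams)

    def __post_init__(self):
        if self.optimizer.lower() != "adam":
            raise ConfigurationError("only the Adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.early_stopping_patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.loss_mode not in ("ce", "composite"):
            raise ConfigurationError(f"unknown loss_mode {self.loss_mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TrainingHistory:
    """Per-epoch train/val records plus stopping bookkeeping (1-based epochs)."""

    epochs: list[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def series(self, key: str) -> list[float]:
        return [e[key] for e in self.epochs]


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without strict improvement."""

    def __init__(self, patience: int = 5, min_delta: float = 0.0):
        if patience < 1:
            raise ConfigurationError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_value = np.inf
        self.best_index = 0
        self.wait = 0

    def update(self, value: float, index: int) -> bool:
        """Record the monitored value for epoch ``index``; True means stop."""
        if value < self.best_value - self.min_delta:
            self.best_value = value
            self.best_index = index
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def _loss_graph(logits: nn.Tensor, y: np.ndarray, cfg: TrainConfig) -> nn.Tensor:
    loss = cross_entropy_graph(logits, y)
    if cfg.loss_mode == "composite":
        probs = nn.softmax(logits, axis=-1)
        loss = (loss
                + cfg.lambda_tversky * tversky_loss_graph(probs, y, cfg.tversky)
                + cfg.lambda_boundary * boundary_loss_graph(probs, y, cfg.boundary))
    return loss


def _prepare(x: np.ndarray, y: np.ndarray, n_classes: int,
             what: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(y)
    if x.ndim != 4 or y.ndim != 3 or x.shape[:3] != y.shape:
        raise DataError(
            f"{what}: images {x.shape} and masks {y.shape} are inconsistent")
    onehot = np.stack([one_hot(m, n_classes) for m in y])
    return x, onehot


def _epoch_metrics(probs: np.ndarray, masks: np.ndarray,
                   onehot: np.ndarray, cfg: TrainConfig) -> dict[str, float]:
    """Macro-averaged hard metrics plus monitored soft losses for one set."""
    pred = np.argmax(probs, axis=-1)
    n_classes = probs.shape[-1]
    acc, prec, sens, spec = [], [], [], []
    for k in range(n_classes):
        c = confusion_counts(masks, pred, k)
        p, a, _ = precision_accuracy_dice(c)
        acc.append(a)
        prec.append(p)
        sens.append(sensitivity(c))
        spec.append(specificity(c))
    return {
        "accuracy": float(np.mean(acc)),
        "precision": float(np.mean(prec)),
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "tversky_loss": tversky_loss(onehot, probs, cfg.tversky),
        "boundary_loss": float(np.mean([
            boundary_loss(onehot[i], probs[i], cfg.boundary)
            for i in range(len(probs))])),
    }


def _forward_in_batches(model: GNet, x: np.ndarray, batch: int) -> np.ndarray:
    out = [model.predict_proba(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(out, axis=0)


def train(model: GNet, data, cfg: TrainConfig | None = None) -> TrainingHistory:
    """Optimize ``model`` and return the per-epoch history.

    ``data`` is either a :class:`~gnet.io_formats.DatasetManifest` with
    non-empty train and val splits, or a tuple
    ``((X_train, y_train), (X_val, y_val))`` of image/mask arrays.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    if hasattr(data, "load_split"):
        x_train, y_train = data.load_split("train")
        x_val, y_val = data.load_split("val")
    else:
        (x_train, y_train), (x_val, y_val) = data
    k = model.config.n_classes
    x_train, t_train = _prepare(x_train, y_train, k, "train split")
    x_val, t_val = _prepare(x_val, y_val, k, "val split")
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)

    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    stopper = EarlyStopping(cfg.early_stopping_patience, cfg.min_delta)
    best_state = model.state_dict()
    history = TrainingHistory(best_epoch=1)
    n = len(x_train)
    logger.info("training: %d train / %d val, config %s, seed %d",
                n, len(x_val), cfg.config_hash(), cfg.seed)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        train_probs = np.empty_like(t_train)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward_logits(nn.Tensor(x_train[idx]))
            loss = _loss_graph(logits, t_train[idx], cfg)
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss ({value}) at epoch {epoch}; "
                    "lower the learning rate or check the input scaling")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
            shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
            e = np.exp(shifted)
            train_probs[idx] = e / e.sum(axis=-1, keepdims=True)

        val_probs = _forward_in_batches(model, x_val, cfg.batch_size)
        val_loss = _loss_graph(
            nn.Tensor(np.log(np.clip(val_probs, 1e-12, 1.0))), t_val, cfg).item()

        record = {"epoch": epoch,
                  "train_loss": float(np.mean(epoch_losses)),
                  "val_loss": float(val_loss)}
        for split, probs, masks, onehot in (
                ("train", train_probs, y_train, t_train),
                ("val", val_probs, y_val, t_val)):
            for name, value in _epoch_metrics(probs, masks, onehot, cfg).items():
                record[f"{split}_{name}"] = value
        history.epochs.append(record)
        logger.info("epoch %d: train_loss=%.4f val_loss=%.4f",
                    epoch, record["train_loss"], record["val_loss"])

        monitored = record[cfg.monitor]
        improved_from = stopper.best_value
        should_stop = stopper.update(monitored, epoch)
        if stopper.best_index == epoch and stopper.wait == 0 \
                and monitored < improved_from:
            best_state = model.state_dict()
            history.best_epoch = epoch
        if cfg.early_stopping and should_stop:
            history.stopped_epoch = epoch
            break
    if history.stopped_epoch == 0:
        history.stopped_epoch = len(history.epochs)
    model.load_state_dict(best_state)
    return history


def train_steps(model: GNet, x: np.ndarray, y: np.ndarray, steps: int,
                cfg: TrainConfig | None = None) -> list[float]:
    """Full-batch gradient steps on a fixed set; returns the loss trace.

    A deliberately minimal loop (no validation, no early stopping) used to
    probe optimization capacity, e.g. overfitting a handful of phantoms.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    x, onehot = _prepare(x, y, model.config.n_classes, "train set")
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    losses = []
    for _ in range(steps):
        logits = model.forward_logits(nn.Tensor(x))
        loss = _loss_graph(logits, onehot, cfg)
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss ({value})")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        losses.append(value)
    return losses
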