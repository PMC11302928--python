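"""Scikit-learn style estimator wrapping the network and training loop.

:class:`GNetSegmenter` is a per-pixel classifier: ``fit`` takes a stack of
2-D grayscale images and integer label masks, ``predict`` returns label
masks, ``predict_proba`` per-pixel class probabilities. It follows the
scikit-learn estimator contract (``get_params``/``set_params``, fitted
attributes with a trailing underscore, ``clone``-ability), so it composes
with sklearn model selection even though its inputs are image stacks rather
than feature matrices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DataError
from .losses_metrics import (BoundaryParams, TverskyParams, confusion_counts,
                             precision_accuracy_dice)
from .model import GNet, GNetConfig
from .train import TrainConfig, train, train_steps

__all__ = ["GNetSegmenter"]


class GNetSegmenter(BaseEstimator):
    """Multi-class 2-D semantic segmentation with the G-Net architecture.

    Parameters mirror the architecture and training configurations; see
    :class:`~gnet.model.GNetConfig` and :class:`~gnet.train.TrainConfig`.

    Attributes (after ``fit``)
    --------------------------
    model_ : GNet
        The trained network.
    history_ : TrainingHistory
        Per-epoch losses and metrics.
    classes_ : ndarray
        The class labels ``0..n_classes-1``.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(self, encoder_filters=(64, 128, 256), se_reduction=16,
                 spp_pool_sizes=(2, 4, 8), spp_filters_per_level=256,
                 spp_include_input=True, n_classes=4, conv_kernel=3,
                 learning_rate=1e-3, max_epochs=50, early_stopping=True,
                 early_stopping_patience=5, batch_size=8, loss_mode="ce",
                 lambda_tversky=1.0, lambda_boundary=1.0,
                 tversky_alpha=0.7, tversky_beta=0.3, boundary_weight=1.0,
                 validation_fraction=0.2, random_state=0):
        self.encoder_filters = encoder_filters
        self.se_reduction = se_reduction
        self.spp_pool_sizes = spp_pool_sizes
        self.spp_filters_per_level = spp_filters_per_level
        self.spp_include_input = spp_include_input
        self.n_classes = n_classes
        self.conv_kernel = conv_kernel
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.early_stopping = early_stopping
        self.early_stopping_patience = early_stopping_patience
        self.batch_size = batch_size
        self.loss_mode = loss_mode
        self.lambda_tversky = lambda_tversky
        self.lambda_boundary = lambda_boundary
        self.tversky_alpha = tversky_alpha
        self.tversky_beta = tversky_beta
        self.boundary_weight = boundary_weight
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- configuration plumbing ---------------------------------------------
    def _as_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4:
            raise DataError(
                f"X must be (n, H, W) or (n, H, W, C), got shape {X.shape}")
        return X

    def _model_config(self, input_size, input_channels) -> GNetConfig:
        return GNetConfig(
            encoder_filters=tuple(self.encoder_filters),
            se_reduction=self.se_reduction,
            spp_pool_sizes=tuple(self.spp_pool_sizes),
            spp_filters_per_level=self.spp_filters_per_level,
            spp_include_input=self.spp_include_input,
            n_classes=self.n_classes,
            conv_kernel=self.conv_kernel,
            input_channels=input_channels,
            input_size=tuple(input_size),
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            early_stopping=self.early_stopping,
            early_stopping_patience=self.early_stopping_patience,
            batch_size=self.batch_size,
            seed=self.random_state,
            loss_mode=self.loss_mode,
            lambda_tversky=self.lambda_tversky,
            lambda_boundary=self.lambda_boundary,
            tversky=TverskyParams(self.tversky_alpha, self.tversky_beta),
            boundary=BoundaryParams(self.boundary_weight),
        )

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train on images ``X`` with label masks ``y``.

        When ``validation_data=(X_val, y_val)`` is absent, the trailing
        ``validation_fraction`` of the training stack is held out to drive
        early stopping.
        """
        X = self._as_images(X)
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise DataError(f"y must be (n, H, W) matching X; "
                            f"got {y.shape} for X {X.shape}")
        self.model_ = GNet(self._model_config(X.shape[1:3], X.shape[3]),
                           seed=self.random_state)
        self.n_parameters_ = self.model_.parameter_count
        self.classes_ = np.arange(self.n_classes)
        if validation_data is not None:
            x_val, y_val = validation_data
            x_val = self._as_images(x_val)
            train_set = (X, y)
        else:
            n_val = max(int(round(len(X) * self.validation_fraction)), 1)
            if n_val >= len(X):
                raise DataError("not enough samples to hold out validation data")
            train_set = (X[:-n_val], y[:-n_val])
            x_val, y_val = X[-n_val:], y[-n_val:]
        self.history_ = train(self.model_, (train_set, (x_val, np.asarray(y_val))),
                              self._train_config())
        return self

    def fit_steps(self, X, y, steps: int):
        """Full-batch optimization for a fixed number of steps (no held-out
        set, no early stopping); records the loss trace in ``loss_trace_``."""
        X = self._as_images(X)
        y = np.asarray(y)
        self.model_ = GNet(self._model_config(X.shape[1:3], X.shape[3]),
                           seed=self.random_state)
        self.n_parameters_ = self.model_.parameter_count
        self.classes_ = np.arange(self.n_classes)
        self.loss_trace_ = train_steps(self.model_, X, y, steps,
                                       self._train_config())
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict_proba(self._as_images(X))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict(self._as_images(X))

    def score(self, X, y) -> float:
        """Mean foreground Dice: per-class Dice over classes 1..K-1 with
        counts pooled over the whole stack, averaged across classes."""
        pred = self.predict(X)
        y = np.asarray(y)
        dices = []
        for k in range(1, self.n_classes):
            c = confusion_counts(y, pred, k)
            dices.append(precision_accuracy_dice(c)[2])
        return float(np.mean(dices))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise DataError("this GNetSegmenter instance is not fitted yet")
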