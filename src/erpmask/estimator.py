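"""Scikit-learn-style estimator wrapping the dynamic masked convolution model.

`DynamicMaskedConvClassifier` exposes the full pipeline — per-sample
variable-length kernel generation, depthwise masked convolution, and the
weighted-loss training protocol — through the familiar ``fit`` /
``predict`` / ``predict_proba`` surface, so it composes with sklearn model
selection utilities that tolerate 3-D inputs of shape (n_trials, n_channels,
n_samples).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import _fast, training
from .model import ModelConfig

__all__ = ["DynamicMaskedConvClassifier"]


class DynamicMaskedConvClassifier(BaseEstimator, ClassifierMixin):
    """Binary ERP classifier with dynamically masked multi-scale kernels.

    Parameters
    ----------
    n_scales : int, default 30
        Number of convolution kernels (scales), K.
    kernel_len : int, default 200
        Base kernel length l in samples; the soft mask truncates within it.
    segment_start : int, default 400
        Start P (samples, 0-based) of the pooled-feature segment [P, P+l)
        that drives mask generation.
    sharpness : float, default 5.0
        Soft-mask sharpness lambda; large values approach a hard 0-1 cutoff.
    variant : {"masked", "standard"}, default "masked"
        "standard" fixes all masks at 1 (plain fixed-length kernels).
    dropout_rate : float, default 0.5
    base_kernels_trainable : bool, default True
    init_std : float, optional
        Gaussian kernel-initialization std; defaults to 1/sqrt(kernel_len).
    learning_rate, weight_decay : float
        AdamW hyperparameters (defaults 1e-5 and 1e-4).
    positive_class_weight : float, default 4.0
        Loss weight on the positive class (the paradigm's inverse class ratio).
    epochs : int, default 100
    batch_size : int, default 32
    threshold : float, default 0.5
        Decision threshold on the positive-class probability; scores at or
        above it predict the positive class.
    optimizer : {"adamw", "sgd"}, default "adamw"
    random_state : int, default 0
        Seeds initialization, batch shuffling and dropout; fits are
        reproducible given the same value.

    Attributes
    ----------
    params_ : ModelParams
        Fitted weights (with config) after :meth:`fit`.
    history_ : dict
        Per-epoch training (and optional validation) loss.
    classes_ : ndarray
        Always ``[0, 1]``.
    n_channels_, n_samples_ : int
        Input dimensions seen during fit.
    """

    def __init__(self, n_scales: int = 30, kernel_len: int = 200,
                 segment_start: int = 400, sharpness: float = 5.0,
                 variant: str = "masked", dropout_rate: float = 0.5,
                 base_kernels_trainable: bool = True,
                 init_std: Optional[float] = None,
                 learning_rate: float = 1e-5, weight_decay: float = 1e-4,
                 positive_class_weight: float = 4.0, epochs: int = 100,
                 batch_size: int = 32, threshold: float = 0.5,
                 optimizer: str = "adamw", random_state: int = 0):
        self.n_scales = n_scales
        self.kernel_len = kernel_len
        self.segment_start = segment_start
        self.sharpness = sharpness
        self.variant = variant
        self.dropout_rate = dropout_rate
        self.base_kernels_trainable = base_kernels_trainable
        self.init_std = init_std
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.positive_class_weight = positive_class_weight
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.optimizer = optimizer
        self.random_state = random_state

    # -- config assembly -----------------------------------------------------

    def _model_config(self, n_channels: int, n_samples: int) -> ModelConfig:
        return ModelConfig(
            n_scales=self.n_scales, kernel_len=self.kernel_len,
            segment_start=self.segment_start, sharpness=self.sharpness,
            n_channels=n_channels, n_samples=n_samples,
            dropout_rate=self.dropout_rate, variant=self.variant,
            base_kernels_trainable=self.base_kernels_trainable,
            init_std=self.init_std)

    def _train_config(self) -> training.TrainConfig:
        return training.TrainConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            positive_class_weight=self.positive_class_weight,
            epochs=self.epochs, batch_size=self.batch_size,
            threshold=self.threshold, optimizer=self.optimizer,
            seed=self.random_state)

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None) -> "DynamicMaskedConvClassifier":
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError(
                f"X must be 3-D (n_trials, n_channels, n_samples); got {X.shape}")
        cfg = self._model_config(X.shape[1], X.shape[2])
        self.params_, self.history_ = training.fit_arrays(
            X, y, cfg, self._train_config(), X_val=X_val, y_val=y_val)
        self.classes_ = np.array([0, 1])
        self.n_channels_ = X.shape[1]
        self.n_samples_ = X.shape[2]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise NotFittedError(
                "this DynamicMaskedConvClassifier instance is not fitted yet")

    def decision_function(self, X) -> np.ndarray:
        """Evaluation-mode logits (deterministic)."""
        self._check_fitted()
        return _fast.predict_logits(np.asarray(X), self.params_)

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        p1 = training._sigmoid(logits)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return (p1 >= self.threshold).astype(np.int64)

    def mask_diagnostics(self, X) -> List:
        """Per-trial :class:`~erpmask.model.MaskDiagnostics` (masked variant only)."""
        self._check_fitted()
        from .model import forward

        return [forward(x, self.params_)[2] for x in np.asarray(X)]
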