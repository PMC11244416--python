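"""Imbalance-weighted training and prediction.

The loss is class-weighted binary cross-entropy on logits: the positive
(probe / self-face) class, outnumbered 1:4 in the paradigm, is up-weighted so
the classifier is not rewarded for collapsing onto the majority class.
Optimization uses adaptive moment estimation with decoupled weight decay by
default (plain SGD available), with the study's hyperparameters as defaults:
learning rate 1e-5, weight decay 1e-4, dropout 0.5, decision threshold 0.5,
positive-class weight equal to the 4:1 inverse class frequency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _fast
from .epochs import EpochSet
from .model import ModelConfig, ModelParams

__all__ = ["TrainConfig", "weighted_bce", "weighted_bce_grad", "fit",
            "fit_arrays", "predict", "predict_scores"]


@dataclass
class TrainConfig:
    """Optimization and protocol hyperparameters."""

    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    positive_class_weight: float = 4.0
    epochs: int = 100
    batch_size: int = 32
    threshold: float = 0.5
    n_folds: int = 3
    train_fraction: float = 0.9
    optimizer: str = "adamw"
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.positive_class_weight <= 0:
            raise ValueError("positive_class_weight must be positive")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer not in ("adamw", "sgd"):
            raise ValueError("optimizer must be 'adamw' or 'sgd'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def weighted_bce(logits: np.ndarray, labels: np.ndarray,
                 positive_class_weight: float = 4.0) -> float:
    """Class-weighted binary cross-entropy on logits.

    Mean over the batch of ``-[w * y * log(sigma(z)) + (1-y) * log(1-sigma(z))]``
    with ``w`` the positive-class weight; computed in the numerically stable
    softplus form.  With ``w = 1`` this is the ordinary binary cross-entropy.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if logits.size == 0:
        raise ValueError("cannot compute a loss on an empty batch")
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits in loss")
    w = positive_class_weight
    per = w * labels * _softplus(-logits) + (1.0 - labels) * _softplus(logits)
    return float(per.mean())


def weighted_bce_grad(logits: np.ndarray, labels: np.ndarray,
                      positive_class_weight: float = 4.0) -> np.ndarray:
    """d(loss)/d(logits) for :func:`weighted_bce` (mean reduction)."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    w = positive_class_weight
    s = _sigmoid(logits)
    return ((1.0 - labels) * s - w * labels * (1.0 - s)) / logits.size


def fit_arrays(X: np.ndarray, y: np.ndarray, model_config: ModelConfig,
               train_config: TrainConfig,
               X_val: Optional[np.ndarray] = None,
               y_val: Optional[np.ndarray] = None,
               dtype=np.float32) -> Tuple[ModelParams, Dict[str, List[float]]]:
    """Core training loop on raw arrays; deterministic given ``train_config.seed``."""
    model_config.validate()
    train_config.validate()
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 3 or len(X) != len(y):
        raise ValueError("X must be (n, C, T) with one label per trial")
    if len(X) == 0:
        raise ValueError("cannot train on an empty dataset")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"training set must contain both classes; found labels {classes.tolist()}")

    rng = np.random.default_rng(train_config.seed)
    params = ModelParams.initialize(model_config, rng)
    if train_config.optimizer == "adamw":
        opt = _fast.AdamW(train_config.learning_rate, train_config.weight_decay)
    else:
        opt = _fast.SGD(train_config.learning_rate, train_config.weight_decay)

    prep = _fast.prepare_data(X, model_config, dtype=dtype)
    prep_val = None
    if X_val is not None:
        prep_val = _fast.prepare_data(np.asarray(X_val), model_config, dtype=dtype)

    n = len(X)
    w = train_config.positive_class_weight
    history: Dict[str, List[float]] = {"train_loss": []}
    if prep_val is not None:
        history["val_loss"] = []

    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            logits, cache = _fast.forward_batch(
                prep, idx, params, model_config, training=True, dropout_rng=rng)
            loss = weighted_bce(logits, y[idx], w)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting at {start}")
            glogits = weighted_bce_grad(logits, y[idx], w)
            grads = _fast.backward_batch(prep, cache, params, model_config, glogits)
            opt.step(params, grads)
            _fast.update_running_stats(params, cache)
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        history["train_loss"].append(epoch_loss / n_seen)
        if prep_val is not None:
            vlogits, _ = _fast.forward_batch(
                prep_val, np.arange(len(X_val)), params, model_config, training=False)
            history["val_loss"].append(weighted_bce(vlogits, y_val, w))
    return params, history


def fit(train: EpochSet, model_config: ModelConfig, train_config: TrainConfig,
        validation: Optional[EpochSet] = None,
        ) -> Tuple[ModelParams, Dict[str, List[float]]]:
    """Train the model on an :class:`EpochSet`.

    Returns the fitted parameters (carrying their config) and a history dict
    with per-epoch mean training loss (and validation loss when a validation
    set is supplied).
    """
    X_val = validation.data if validation is not None else None
    y_val = validation.labels if validation is not None else None
    return fit_arrays(train.data, train.labels, model_config, train_config,
                      X_val=X_val, y_val=y_val)


def predict_scores(params: ModelParams, es: EpochSet) -> np.ndarray:
    """Evaluation-mode class-1 probabilities, one per trial, strictly in (0, 1)."""
    logits = _fast.predict_logits(es.data, params)
    return _sigmoid(logits)


def predict(params: ModelParams, es: EpochSet,
            threshold: float = 0.5) -> Tuple[np.ndarray, np.ndarray]:
    """Scores and thresholded labels; a score exactly at the threshold is positive."""
    scores = predict_scores(params, es)
    return scores, (scores >= threshold).astype(np.int64)
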