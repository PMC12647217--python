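"""Lightweight MLP over the selected feature subset.

Standardized inputs (zero mean, unit variance) feed a (256, 128, 64) ReLU
network trained with mini-batch SGD, an adaptive learning rate (divide by 5
whenever the validation score stalls), L2 penalty 5e-4, and early stopping on
a 10% stratified validation split with patience 10.  These defaults are the
hyperparameters the selection pipeline is evaluated with; everything is
overridable through :class:`MLPConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .feature_graph import FeatureMatrix

__all__ = ["MLPConfig", "TrainedModel", "fit", "predict", "save_model", "load_model"]


@dataclass
class MLPConfig:
    hidden_sizes: tuple[int, int, int] = (256, 128, 64)
    activation: str = "relu"
    optimizer: str = "sgd"
    lr_init: float = 0.01
    lr_policy: str = "adaptive"
    l2_alpha: float = 0.0005
    batch_size: int = 64
    max_iter: int = 500
    early_stop: bool = True
    val_frac: float = 0.10
    patience: int = 10
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0.0 < self.val_frac < 1.0:
            raise ValueError("val_frac must lie in (0, 1)")
        if min(self.lr_init, self.l2_alpha) < 0 or self.batch_size < 1 or self.max_iter < 1:
            raise ValueError("numeric hyperparameters must be positive")
        if self.activation != "relu" or self.optimizer != "sgd" or self.lr_policy != "adaptive":
            raise ValueError("supported configuration is relu + sgd + adaptive lr")


@dataclass
class TrainedModel:
    """Fitted scaler + network, with the training history and class list."""

    scaler: StandardScaler
    mlp: MLPClassifier
    config: MLPConfig
    classes: np.ndarray
    history: list[float] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return int(self.mlp.n_iter_)


def _balanced_oversample(
    x: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded oversampling to equal class counts (stand-in for n/(C*n_c) loss weights)."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    rows = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        rows.append(idx)
        if count < target:
            rows.append(rng.choice(idx, size=target - count, replace=True))
    rows = np.concatenate(rows)
    rng.shuffle(rows)
    return x[rows], y[rows]


def fit(features: FeatureMatrix, cfg: MLPConfig | None = None) -> TrainedModel:
    """Train the MLP on the (already column-selected) feature matrix.

    The scaler is fitted on the training data only; the early-stopping
    validation split is carved out of the standardized training data by the
    network itself (stratified, seeded).
    """
    if cfg is None:
        cfg = MLPConfig()
    x = features.values
    y = features.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if cfg.class_weighting:
        x, y = _balanced_oversample(x, y, cfg.seed)

    if np.any(x.var(axis=0) == 0):
        warnings.warn("zero-variance feature columns: scale replaced by 1", stacklevel=2)
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)

    mlp = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_sizes,
        activation=cfg.activation,
        solver=cfg.optimizer,
        alpha=cfg.l2_alpha,
        batch_size=min(cfg.batch_size, x.shape[0]),
        learning_rate=cfg.lr_policy,
        learning_rate_init=cfg.lr_init,
        max_iter=cfg.max_iter,
        early_stopping=cfg.early_stop,
        validation_fraction=cfg.val_frac,
        n_iter_no_change=cfg.patience,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        # max_iter is a hard budget by design; hitting it is not an error here
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(xs, y)
    return TrainedModel(
        scaler=scaler,
        mlp=mlp,
        config=cfg,
        classes=mlp.classes_,
        history=list(mlp.loss_curve_),
    )


def predict(
    model: TrainedModel, features: FeatureMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class-probability matrix for new samples."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.ndim != 2 or x.shape[1] != model.scaler.mean_.size:
        raise ValueError(
            f"feature count {x.shape[-1] if x.ndim == 2 else '?'} does not match "
            f"the {model.scaler.mean_.size} training columns"
        )
    xs = model.scaler.transform(x)
    proba = model.mlp.predict_proba(xs)
    labels = model.classes[np.argmax(proba, axis=1)]
    return labels, proba


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist scaler + weights + config + class list as one archive."""
    joblib.dump(
        {
            "scaler": model.scaler,
            "mlp": model.mlp,
            "config": model.config,
            "classes": model.classes,
            "history": model.history,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(
        scaler=blob["scaler"],
        mlp=blob["mlp"],
        config=blob["config"],
        classes=blob["classes"],
        history=blob["history"],
    )
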