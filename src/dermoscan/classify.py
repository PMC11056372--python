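"""Benign/malignant classification of lesion feature vectors.

Two classifiers over standardized features: a small feed-forward neural
network (one hidden layer of 16 logistic units by default) and a kernel SVM
(RBF by default).  Both are wrapped in an sklearn pipeline whose scaler is
fitted on the training set only and re-applied verbatim at predict time.
Splitting is stratified and seed-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledDataset",
    "AnnConfig",
    "SvmConfig",
    "TrainedClassifier",
    "split_dataset",
    "train_ann",
    "train_svm",
    "predict",
]


@dataclass
class LabeledDataset:
    """Feature matrix plus per-sample labels and ids."""

    X: pd.DataFrame
    y: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths disagree")
        if self.ids is not None and len(self.ids) != len(self.y):
            raise ValueError("ids length disagrees with y")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class AnnConfig:
    """Feed-forward network settings.

    The default solver is full-batch L-BFGS, the reliable choice at the
    dataset sizes this pipeline targets (~10^2 samples); with a stochastic
    solver ("adam"/"sgd") training instead uses validation-based early
    stopping on ``validation_fraction`` of the training data.
    """

    hidden_layers: tuple[int, ...] = (16,)
    activation: str = "logistic"
    solver: str = "lbfgs"
    max_epochs: int = 500
    validation_fraction: float = 0.1
    learning_rate: float = 0.01  # logistic units train too slowly at adam's default
    seed: int = 0


@dataclass
class SvmConfig:
    kernel: str = "rbf"
    c: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0


@dataclass
class TrainedClassifier:
    """A fitted model: kind, sklearn pipeline (scaler + estimator), config echo."""

    kind: str
    pipeline: Pipeline
    n_features: int
    feature_names: list[str] | None
    config: AnnConfig | SvmConfig
    warnings: list[str] = field(default_factory=list)


def split_dataset(
    data: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random split; exact partition, deterministic per seed."""
    if not (0 < train_fraction < 1):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    classes, counts = np.unique(data.y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for a stratified split")
    idx = np.arange(len(data))
    tr, te = train_test_split(
        idx, train_size=train_fraction, stratify=data.y, random_state=seed
    )
    tr = np.sort(tr)
    te = np.sort(te)

    def _take(ii: np.ndarray) -> LabeledDataset:
        return LabeledDataset(
            X=data.X.iloc[ii].reset_index(drop=True),
            y=data.y[ii],
            ids=[data.ids[k] for k in ii] if data.ids is not None else None,
        )

    return _take(tr), _take(te)


def _validate_training(data: LabeledDataset) -> None:
    if len(np.unique(data.y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    values = data.X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = data.X.columns[~np.isfinite(values).all(axis=0)].tolist()
        raise ValueError(f"non-finite features in training data: {bad}")


def _fit(kind: str, estimator, data: LabeledDataset, config) -> TrainedClassifier:
    pipe = Pipeline([("scale", StandardScaler()), ("model", estimator)])
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always", ConvergenceWarning)
        pipe.fit(data.X.to_numpy(dtype=float), data.y)
        caught = [str(x.message) for x in w if issubclass(x.category, ConvergenceWarning)]
    return TrainedClassifier(
        kind=kind,
        pipeline=pipe,
        n_features=data.X.shape[1],
        feature_names=list(data.X.columns),
        config=config,
        warnings=caught,
    )


def train_ann(train: LabeledDataset, config: AnnConfig | None = None) -> TrainedClassifier:
    """Fit the feed-forward network (standardized inputs, validation hold-out).

    Non-convergence within ``max_epochs`` is recorded as a warning on the
    returned model, not raised.
    """
    cfg = config or AnnConfig()
    _validate_training(train)
    kwargs = dict(
        hidden_layer_sizes=cfg.hidden_layers,
        activation=cfg.activation,
        solver=cfg.solver,
        max_iter=cfg.max_epochs,
        random_state=cfg.seed,
    )
    if cfg.solver in ("adam", "sgd"):
        kwargs.update(
            early_stopping=True,
            validation_fraction=cfg.validation_fraction,
            learning_rate_init=cfg.learning_rate,
            n_iter_no_change=25,
        )
    est = MLPClassifier(**kwargs)
    return _fit("ann", est, train, cfg)


def train_svm(train: LabeledDataset, config: SvmConfig | None = None) -> TrainedClassifier:
    """Fit the kernel SVM on standardized inputs."""
    cfg = config or SvmConfig()
    _validate_training(train)
    est = SVC(kernel=cfg.kernel, C=cfg.c, gamma=cfg.gamma, random_state=cfg.seed)
    return _fit("svm", est, train, cfg)


def predict(model: TrainedClassifier, vectors: pd.DataFrame | np.ndarray | Sequence) -> np.ndarray:
    """One label per row; deterministic given the fitted model."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0, model.n_features) if X.size == 0 else X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    return model.pipeline.predict(X)
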