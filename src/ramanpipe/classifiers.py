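"""Classifier families: four classical models and two 1-D conv architectures.

Classical families (logistic regression, RBF-kernel SVM, random forest,
XGBoost) are configured scikit-learn / xgboost estimators.  The deep families
are a compact two-conv-layer 1D-CNN and a three-block 1D-ResNet expressed in
the package's own numpy network engine; both end in a single sigmoid unit and
carry an L2 weight penalty of 1e-4, and are trained for 40 epochs with Adam
at learning rate 1e-3 on binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import nn

__all__ = [
    "ML_FAMILIES",
    "DL_FAMILIES",
    "ModelSpec",
    "TrainRecipe",
    "TrainedModel",
    "build_ml_model",
    "build_cnn1d",
    "build_resnet1d",
    "train_dl",
    "fit_model",
]

ML_FAMILIES = ("logreg", "svm", "random_forest", "xgboost")
DL_FAMILIES = ("cnn1d", "resnet1d")

#: L2 regularization strength shared by XGBoost and the deep models.
L2_STRENGTH = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameter overrides and a seed."""

    family: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ML_FAMILIES + DL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; expected one of "
                f"{ML_FAMILIES + DL_FAMILIES}"
            )

    @property
    def is_deep(self) -> bool:
        return self.family in DL_FAMILIES


@dataclass
class TrainRecipe:
    """Deep-model training schedule: 40 epochs of Adam at lr 1e-3 on BCE."""

    epochs: int = 40
    lr: float = 1e-3
    batch_size: int = 32
    seed: int = 0


@dataclass
class TrainedModel:
    """A fitted classifier with a uniform probability interface."""

    spec: ModelSpec
    estimator: Any  # sklearn-like estimator or nn.Sequential
    meta: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(cancerous) per row, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        if isinstance(self.estimator, nn.Sequential):
            return self.estimator.predict_proba(X[:, None, :])
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels at the 0.5 probability threshold."""
        return (self.predict_proba(X) >= 0.5).astype(int)


def build_ml_model(spec: ModelSpec):
    """Configured, seeded, unfitted classical estimator.

    Defaults: logreg with L2 penalty; SVM with RBF kernel, C=1; random forest
    with 100 trees; XGBoost with 200 rounds, learning rate 0.1, depth 3 and
    ridge (L2) regularization 1e-4.  Any default can be overridden through
    ``spec.hyperparams``.
    """
    if spec.family not in ML_FAMILIES:
        raise ValueError(f"{spec.family!r} is not a classical family; use build_cnn1d/build_resnet1d")
    hp = dict(spec.hyperparams)
    if spec.family == "logreg":
        # sklearn's default penalty is already ridge (L2)
        return LogisticRegression(
            C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 2000),
            random_state=spec.seed, **hp,
        )
    if spec.family == "svm":
        return SVC(
            kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0), probability=True,
            random_state=spec.seed, **hp,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=spec.seed, n_jobs=1, **hp,
        )
    return XGBClassifier(
        n_estimators=hp.pop("n_estimators", 200),
        learning_rate=hp.pop("learning_rate", 0.1),
        max_depth=hp.pop("max_depth", 3),
        reg_lambda=hp.pop("l2_strength", L2_STRENGTH),
        random_state=spec.seed, n_jobs=1, eval_metric="logloss", **hp,
    )


def build_cnn1d(input_length: int, seed: int = 0, dropout: float = 0.25,
                l2: float = L2_STRENGTH) -> nn.Sequential:
    """Two-stage 1D-CNN for binary spectral classification.

    conv(10 filters, kernel 3) -> ReLU -> batch norm -> dropout ->
    conv(25 filters, kernel 3) -> ReLU -> batch norm -> dropout ->
    average pool(8) -> flatten -> dense(1) -> sigmoid (in the loss/predict).
    'Same' convolution padding keeps feature maps aligned with the spectrum
    axis, which the saliency maps rely on.
    """
    if input_length < 32:
        raise ValueError(f"input_length must be >= 32, got {input_length}")
    rng = np.random.default_rng(seed)
    pooled = input_length // 8
    model = nn.Sequential([
        nn.Conv1D(1, 10, 3, rng, l2),
        nn.ReLU(),
        nn.BatchNorm1D(10),
        nn.Dropout(dropout, rng),
        nn.Conv1D(10, 25, 3, rng, l2),
        nn.ReLU(),
        nn.BatchNorm1D(25),
        nn.Dropout(dropout, rng),
        nn.AvgPool1D(8),
        nn.Flatten(),
        nn.Dense(25 * pooled, 1, rng, l2),
    ])
    model.summary = {  # type: ignore[attr-defined]
        "architecture": "cnn1d",
        "conv_filters": [10, 25],
        "kernel_size": 3,
        "pool_size": 8,
        "dropout": dropout,
        "l2_strength": l2,
        "input_length": input_length,
    }
    return model


def build_resnet1d(input_length: int, seed: int = 0, l2: float = L2_STRENGTH) -> nn.Sequential:
    """Three-residual-block 1D-ResNet (16/32/64 channels) with global pooling."""
    if input_length < 64:
        raise ValueError(f"input_length must be >= 64, got {input_length}")
    rng = np.random.default_rng(seed)
    model = nn.Sequential([
        nn.ResidualBlock1D(1, 16, rng, l2),
        nn.ResidualBlock1D(16, 32, rng, l2),
        nn.ResidualBlock1D(32, 64, rng, l2),
        nn.GlobalAvgPool1D(),
        nn.Dense(64, 1, rng, l2),
    ])
    model.summary = {  # type: ignore[attr-defined]
        "architecture": "resnet1d",
        "blocks": 3,
        "block_channels": [16, 32, 64],
        "kernel_size": 3,
        "l2_strength": l2,
        "input_length": input_length,
    }
    return model


def train_dl(
    network: nn.Sequential,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    recipe: TrainRecipe | None = None,
    spec: ModelSpec | None = None,
) -> TrainedModel:
    """Mini-batch Adam training on binary cross-entropy.

    Inputs are (n, length) preprocessed spectra; a singleton channel axis is
    added internally.  Returns the trained model with per-epoch loss history
    (and validation loss when a validation set is given).  A NaN loss aborts
    with a diagnostic rather than training on silently.
    """
    recipe = recipe or TrainRecipe()
    X = np.asarray(X_train, dtype=float)[:, None, :]
    y = np.asarray(y_train, dtype=float)
    rng = np.random.default_rng(recipe.seed)
    opt = nn.Adam(network, lr=recipe.lr)
    history: list[float] = []
    val_history: list[float] = []
    n = X.shape[0]
    for epoch in range(recipe.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, recipe.batch_size):
            idx = order[start : start + recipe.batch_size]
            logits = network.forward(X[idx], training=True)
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            loss += network.l2_loss()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch start {start}; "
                    "try a lower learning rate"
                )
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if X_val is not None and y_val is not None:
            vl, _ = nn.bce_with_logits(
                network.forward(np.asarray(X_val, dtype=float)[:, None, :], training=False),
                np.asarray(y_val, dtype=float),
            )
            val_history.append(float(vl))
    meta = {"epochs": recipe.epochs, "lr": recipe.lr, "loss_history": history}
    if val_history:
        meta["val_loss_history"] = val_history
    return TrainedModel(spec=spec or ModelSpec("cnn1d", seed=recipe.seed), estimator=network, meta=meta)


def fit_model(spec: ModelSpec, X_train: np.ndarray, y_train: np.ndarray,
              recipe: TrainRecipe | None = None) -> TrainedModel:
    """Train any family on a feature/spectrum matrix; uniform entry point."""
    if spec.is_deep:
        builder = build_cnn1d if spec.family == "cnn1d" else build_resnet1d
        hp = dict(spec.hyperparams)
        net = builder(X_train.shape[1], seed=spec.seed, **hp)
        recipe = recipe or TrainRecipe(seed=spec.seed)
        return train_dl(net, X_train, y_train, recipe=recipe, spec=spec)
    est = build_ml_model(spec)
    est.fit(np.asarray(X_train, dtype=float), np.asarray(y_train, dtype=int))
    return TrainedModel(spec=spec, estimator=est, meta={})
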