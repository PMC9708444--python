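"""MLP regression of model accuracy (GDT-TS) from the 19-feature descriptor.

The regressor is a multi-layer perceptron with 5 fully connected hidden
layers of 100 neurons, logistic-sigmoid activation and an Adam optimiser,
trained for at most 500 iterations on min-max-scaled features.  Training
is fully deterministic given the seed; cross-validation is grouped by
protein target so that decoys of one target never straddle a fold
boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy.stats import pearsonr
from sklearn.model_selection import GroupKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import MinMaxScaler

from .errors import GroupingError, ModelIOError, ValidationError
from .features import FEATURE_NAMES

_ARCHIVE_FORMAT = "protqa-qamodel-1"
N_FEATURES = 19


def feature_order_hash(names: Sequence[str] = FEATURE_NAMES) -> str:
    return hashlib.sha256(",".join(names).encode()).hexdigest()[:16]


@dataclasses.dataclass
class ModelConfig:
    """Architecture and optimiser settings.

    Defaults: 5 hidden layers of 100 neurons, logistic activation, Adam
    (learning rate 1e-3, beta1 0.9, beta2 0.999), batch size 200, at most
    500 iterations, no early stopping.  Alternative activations/solvers
    are accepted for comparison runs but only the default is tuned.
    """

    hidden_layers: tuple[int, ...] = (100, 100, 100, 100, 100)
    activation: str = "logistic"
    solver: str = "adam"
    learning_rate_init: float = 1e-3
    beta_1: float = 0.9
    beta_2: float = 0.999
    max_iterations: int = 500
    batch_size: int = 200
    tol: float = 1e-6
    early_stopping: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_layers):
            raise ValidationError("hidden layer sizes must be positive")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class QAModel:
    """A trained accuracy predictor: scaler + MLP + provenance metadata."""

    estimator: MLPRegressor
    scaler: MinMaxScaler
    config: ModelConfig
    feature_hash: str
    n_samples: int
    loss_curve: list[float]

    def predict(self, features: np.ndarray,
                feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != N_FEATURES:
            raise ValidationError(
                f"feature matrix has width {X.shape[1]}, expected {N_FEATURES}")
        if feature_names is not None and feature_order_hash(feature_names) != self.feature_hash:
            raise ValidationError("feature order does not match the trained model")
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite feature values")
        pred = self.estimator.predict(self.scaler.transform(X))
        return np.clip(pred, 0.0, 1.0)


def predict(model: QAModel, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


def train(
    features: np.ndarray,
    targets: np.ndarray,
    config: Optional[ModelConfig] = None,
) -> QAModel:
    """Fit the accuracy predictor; deterministic for a fixed config seed."""
    config = config or ModelConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValidationError(f"expected n x {N_FEATURES} feature matrix, got {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and targets disagree in length")
    if X.shape[0] < 100:
        raise ValidationError(f"need at least 100 training rows, got {X.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in training data")
    if y.min() < 0.0 or y.max() > 1.0:
        raise ValidationError("targets must lie in [0, 1]")

    scaler = MinMaxScaler().fit(X)
    est = MLPRegressor(
        hidden_layer_sizes=config.hidden_layers,
        activation=config.activation,
        solver=config.solver,
        learning_rate_init=config.learning_rate_init,
        beta_1=config.beta_1,
        beta_2=config.beta_2,
        max_iter=config.max_iterations,
        batch_size=min(config.batch_size, X.shape[0]),
        tol=config.tol,
        early_stopping=config.early_stopping,
        n_iter_no_change=config.max_iterations,
        random_state=config.seed,
    )
    import warnings
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(scaler.transform(X), y)
    return QAModel(estimator=est, scaler=scaler, config=config,
                   feature_hash=feature_order_hash(), n_samples=X.shape[0],
                   loss_curve=[float(v) for v in est.loss_curve_])


@dataclasses.dataclass
class CvReport:
    """Grouped k-fold cross-validation metrics on held-out folds."""

    k: int
    fold_mse: list[float]
    fold_mae: list[float]
    fold_pearson: list[float]

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mse))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))

    @property
    def mean_pearson(self) -> float:
        return float(np.mean(self.fold_pearson))

    def summary(self) -> dict[str, float]:
        return {
            "k": self.k,
            "mse_mean": self.mean_mse, "mse_sd": float(np.std(self.fold_mse, ddof=1)),
            "mae_mean": self.mean_mae, "mae_sd": float(np.std(self.fold_mae, ddof=1)),
            "r_mean": self.mean_pearson, "r_sd": float(np.std(self.fold_pearson, ddof=1)),
        }


def cross_validate(
    features: np.ndarray,
    targets: np.ndarray,
    groups: Sequence,
    k: int = 10,
    config: Optional[ModelConfig] = None,
) -> CvReport:
    """k-fold cross-validation with folds split by target group.

    All decoys of one target share a fold, so no structure of a held-out
    target ever contributes to the training side of its own fold.
    """
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if n_groups < k:
        raise GroupingError(f"{n_groups} distinct groups < k={k}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    fold_mse, fold_mae, fold_r = [], [], []
    for train_idx, test_idx in GroupKFold(n_splits=k).split(X, y, groups):
        assert not set(groups[train_idx]) & set(groups[test_idx])
        model = train(X[train_idx], y[train_idx], config)
        pred = model.predict(X[test_idx])
        err = pred - y[test_idx]
        fold_mse.append(float(np.mean(err ** 2)))
        fold_mae.append(float(np.mean(np.abs(err))))
        fold_r.append(float(pearsonr(pred, y[test_idx])[0]))
    return CvReport(k=k, fold_mse=fold_mse, fold_mae=fold_mae, fold_pearson=fold_r)


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: QAModel, path: str | Path) -> None:
    payload = {
        "format": _ARCHIVE_FORMAT,
        "config": model.config.as_dict(),
        "feature_hash": model.feature_hash,
        "n_samples": model.n_samples,
        "loss_curve": model.loss_curve,
        "estimator": model.estimator,
        "scaler": model.scaler,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> QAModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"cannot load model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _ARCHIVE_FORMAT:
        raise ModelIOError(f"{path}: not a compatible model archive")
    cfg = payload["config"]
    cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
    return QAModel(
        estimator=payload["estimator"],
        scaler=payload["scaler"],
        config=ModelConfig(**cfg),
        feature_hash=payload["feature_hash"],
        n_samples=payload["n_samples"],
        loss_curve=payload["loss_curve"],
    )
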