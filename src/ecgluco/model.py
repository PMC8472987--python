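"""Classifiers over the beat-level feature matrix.

The primary model is a 10-layer fully connected network — nine hidden
layers of 500 rectified units and a single sigmoid output — trained with
plain SGD (learning rate 1e-4), the rate halved after 20 epochs without
validation-loss improvement, early stopping after 100 such epochs with
the best weights restored, capped at 1000 epochs.

The interface follows the statsmodels convention: a model object is
built from data, ``fit()`` returns a results object that carries the
fitted network, its training history and evaluation helpers, and
``summary()`` renders a human-readable table.  Reference baselines
(logistic regression C=5, linear SVM C=50, polynomial SVM degree 6,
Gaussian SVM C=2, all capped at 10,000 iterations) use scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from . import evaluation
from .features import feature_array
from .nn import MLP, TrainSchedule, TrainingError


@dataclass
class DnnConfig:
    """Architecture + schedule of the deep classifier."""

    n_hidden_layers: int = 9
    hidden_units: int = 500
    hidden_activation: str = "relu"
    learning_rate: float = 1e-4
    lr_halving_patience: int = 20
    early_stop_patience: int = 100
    max_epochs: int = 1000
    batch_size: int = 32
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5)")
        if self.lr_halving_patience >= self.max_epochs or self.early_stop_patience >= self.max_epochs:
            # patience larger than the epoch budget silently disables the
            # schedule; tolerate but clamp nothing — the cap dominates.
            pass

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return (self.hidden_units,) * self.n_hidden_layers

    def schedule(self) -> TrainSchedule:
        return TrainSchedule(
            learning_rate=self.learning_rate,
            lr_patience=self.lr_halving_patience,
            es_patience=self.early_stop_patience,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )


@dataclass
class BaselineConfig:
    """One of the reference model families with its printed hyperparameter."""

    family: str  # logistic | svm-linear | svm-poly | svm-rbf | baseline-ann
    max_iter: int = 10_000
    seed: int = 0
    params: dict = field(default_factory=dict)

    KNOWN = ("logistic", "svm-linear", "svm-poly", "svm-rbf")

    def __post_init__(self) -> None:
        if self.family not in self.KNOWN:
            raise ValueError(f"unknown baseline family {self.family!r}")


DEFAULT_BASELINES = (
    BaselineConfig("logistic", params={"C": 5.0}),
    BaselineConfig("svm-linear", params={"C": 50.0}),
    BaselineConfig("svm-poly", params={"degree": 6}),
    BaselineConfig("svm-rbf", params={"C": 2.0}),
)


class HyperglycemiaNet:
    """Deep MLP hyperglycemia classifier over standardized beat features.

    Parameters
    ----------
    endog : array-like
        Binary labels, one per beat.
    exog : array-like
        Standardized feature matrix (beats x features).
    config : DnnConfig
    """

    def __init__(self, endog, exog, config: DnnConfig | None = None) -> None:
        self.endog = np.asarray(endog, dtype=int).ravel()
        self.exog = np.asarray(exog, dtype=np.float32)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise ValueError("exog must be 2-D with one row per label")
        if len(np.unique(self.endog)) < 2:
            raise TrainingError("training data contains a single class")
        self.config = config or DnnConfig()

    @classmethod
    def from_feature_matrix(
        cls, matrix: pd.DataFrame, config: DnnConfig | None = None
    ) -> "HyperglycemiaNet":
        X, y = feature_array(matrix)
        return cls(y, X, config=config)

    def fit(self) -> "HyperglycemiaNetResults":
        cfg = self.config
        X_tr, X_val, y_tr, y_val = train_test_split(
            self.exog,
            self.endog,
            test_size=cfg.validation_fraction,
            stratify=self.endog,
            random_state=cfg.seed,
            shuffle=True,
        )
        net = MLP(
            n_inputs=self.exog.shape[1],
            hidden_sizes=cfg.hidden_sizes,
            hidden_activation=cfg.hidden_activation,
            seed=cfg.seed,
        )
        history = net.fit(X_tr, y_tr, X_val, y_val, schedule=cfg.schedule())
        return HyperglycemiaNetResults(model=self, net=net, history=history)


class HyperglycemiaNetResults:
    """Fitted deep classifier: scores, evaluation and summary."""

    def __init__(self, model: HyperglycemiaNet, net: MLP, history: pd.DataFrame) -> None:
        self.model = model
        self.net = net
        self.history = history

    @property
    def n_epochs(self) -> int:
        return int(self.history["epoch"].iloc[-1])

    @property
    def best_val_loss(self) -> float:
        return float(self.history["val_loss"].min())

    def predict_scores(self, matrix) -> np.ndarray:
        """Per-beat scores in [0, 1]; accepts a feature matrix DataFrame
        or a raw array with the training feature count."""
        if isinstance(matrix, pd.DataFrame):
            X, _ = feature_array(matrix)
        else:
            X = np.asarray(matrix, dtype=np.float32)
        if X.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"expected {self.model.exog.shape[1]} features, got {X.shape[1]}"
            )
        return self.net.predict_proba(X)

    def evaluate(
        self, matrix: pd.DataFrame, threshold: float | str = 0.5
    ) -> evaluation.EvaluationReport:
        scores = self.predict_scores(matrix)
        labels = matrix["label"].to_numpy()
        report = evaluation.evaluate_scores(
            scores,
            labels,
            threshold=threshold,
            model_name="deep-mlp",
            config=asdict(self.model.config),
        )
        return report

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Deep MLP hyperglycemia classifier",
            "=" * 48,
            f"hidden layers:        {cfg.n_hidden_layers} x {cfg.hidden_units} ({cfg.hidden_activation})",
            f"output:               1 sigmoid unit",
            f"optimizer:            SGD, lr {cfg.learning_rate:g}, batch {cfg.batch_size}",
            f"lr halving patience:  {cfg.lr_halving_patience} epochs",
            f"early stop patience:  {cfg.early_stop_patience} epochs (cap {cfg.max_epochs})",
            f"training samples:     {len(self.model.endog)}",
            f"epochs run:           {self.n_epochs}",
            f"best val loss (BCE):  {self.best_val_loss:.4f}",
            f"final learning rate:  {float(self.history['lr'].iloc[-1]):g}",
        ]
        return "\n".join(lines)


def train_dnn(
    train_matrix: pd.DataFrame, config: DnnConfig | None = None
) -> HyperglycemiaNetResults:
    """Functional wrapper: fit the deep classifier on a feature matrix."""
    return HyperglycemiaNet.from_feature_matrix(train_matrix, config=config).fit()


# ---------------------------------------------------------------------------
# baselines


class BaselineResults:
    """Fitted scikit-learn baseline with a uniform scoring interface."""

    def __init__(self, estimator, config: BaselineConfig, converged: bool, n_features: int):
        self.estimator = estimator
        self.config = config
        self.converged = converged
        self.n_features = n_features

    def predict_scores(self, matrix) -> np.ndarray:
        if isinstance(matrix, pd.DataFrame):
            X, _ = feature_array(matrix)
        else:
            X = np.asarray(matrix, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        # map SVM decision values through a sigmoid to the unit interval
        return 1.0 / (1.0 + np.exp(-self.estimator.decision_function(X)))

    def evaluate(self, matrix: pd.DataFrame, threshold: float | str = 0.5):
        scores = self.predict_scores(matrix)
        report = evaluation.evaluate_scores(
            scores,
            matrix["label"].to_numpy(),
            threshold=threshold,
            model_name=self.config.family,
            config={**self.config.params, "max_iter": self.config.max_iter,
                    "converged": self.converged},
        )
        return report


def _make_estimator(config: BaselineConfig):
    p = config.params
    if config.family == "logistic":
        return LogisticRegression(C=p.get("C", 5.0), max_iter=config.max_iter)
    if config.family == "svm-linear":
        return SVC(kernel="linear", C=p.get("C", 50.0), max_iter=config.max_iter,
                   random_state=config.seed)
    if config.family == "svm-poly":
        return SVC(kernel="poly", degree=p.get("degree", 6), C=p.get("C", 1.0),
                   max_iter=config.max_iter, random_state=config.seed)
    if config.family == "svm-rbf":
        return SVC(kernel="rbf", C=p.get("C", 2.0), max_iter=config.max_iter,
                   random_state=config.seed)
    raise ValueError(config.family)


def train_baseline(train_matrix: pd.DataFrame, config: BaselineConfig) -> BaselineResults:
    """Fit one reference family on a standardized feature matrix."""
    X, y = feature_array(train_matrix)
    est = _make_estimator(config)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return BaselineResults(est, config, converged, n_features=X.shape[1])
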