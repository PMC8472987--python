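"""A small NumPy multilayer perceptron for binary classification.

Implements exactly the training schedule used by the classifier stack:
plain stochastic gradient descent on binary cross-entropy, learning
rate halved whenever the validation loss fails to improve for
``lr_patience`` consecutive epochs, early stopping after
``es_patience`` epochs without improvement (restoring the best
weights), capped at ``max_epochs``.  All randomness (weight
initialization, mini-batch shuffling) flows from a single integer seed,
so training is bit-reproducible on one machine.

Arithmetic is float32 throughout; losses are accumulated in float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class TrainingError(RuntimeError):
    pass


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


ACTIVATIONS = {"relu": _relu, "tanh": _tanh}


@dataclass
class TrainSchedule:
    learning_rate: float = 1e-4
    lr_patience: int = 20
    es_patience: int = 100
    max_epochs: int = 1000
    batch_size: int = 32
    seed: int = 0


class MLP:
    """Feed-forward net: dense hidden layers + a single sigmoid output."""

    def __init__(
        self,
        n_inputs: int,
        hidden_sizes: tuple[int, ...],
        hidden_activation: str = "relu",
        seed: int = 0,
    ) -> None:
        if hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {hidden_activation!r}")
        self.hidden_activation = hidden_activation
        self.hidden_sizes = tuple(hidden_sizes)
        rng = np.random.default_rng(seed)
        sizes = [n_inputs, *hidden_sizes, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            if hidden_activation == "relu":
                scale = np.sqrt(2.0 / fan_in)  # He init
            else:
                scale = np.sqrt(1.0 / fan_in)  # Xavier-ish for tanh
            self.weights.append(
                rng.normal(0.0, scale, size=(fan_in, fan_out)).astype(np.float32)
            )
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    # -- forward ----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        act = ACTIVATIONS[self.hidden_activation]
        a = X
        activations = [a]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = act(a @ W + b)
            activations.append(a)
        logits = (a @ self.weights[-1] + self.biases[-1]).ravel()
        return activations, logits

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        _, logits = self._forward(np.asarray(X, dtype=np.float32))
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid scores in [0, 1], one per row."""
        logits = self.predict_logits(X).astype(np.float64)
        return 1.0 / (1.0 + np.exp(-logits))

    # -- training ---------------------------------------------------------
    @staticmethod
    def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
        z = logits.astype(np.float64)
        # log(1 + e^z) computed stably
        return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))

    def _step(self, X: np.ndarray, y: np.ndarray, lr: float) -> None:
        activations, logits = self._forward(X)
        p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        n = len(y)
        delta = ((p - y) / n).astype(np.float32)[:, None]  # dL/dlogits
        grads_W: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
        grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore
        grads_W[-1] = activations[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        back = delta @ self.weights[-1].T
        for layer in range(len(self.weights) - 2, -1, -1):
            a_out = activations[layer + 1]
            if self.hidden_activation == "relu":
                back = back * (a_out > 0)
            else:
                back = back * (1.0 - a_out**2)
            grads_W[layer] = activations[layer].T @ back
            grads_b[layer] = back.sum(axis=0)
            if layer > 0:
                back = back @ self.weights[layer].T
        for k in range(len(self.weights)):
            self.weights[k] -= np.float32(lr) * grads_W[k]
            self.biases[k] -= np.float32(lr) * grads_b[k]

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        schedule: TrainSchedule = TrainSchedule(),
    ) -> pd.DataFrame:
        """Train in place; returns the per-epoch history table
        (epoch, lr, train_loss, val_loss)."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64).ravel()
        X_val = np.asarray(X_val, dtype=np.float32)
        y_val = np.asarray(y_val, dtype=np.float64).ravel()
        if len(np.unique(y)) < 2:
            raise TrainingError("training data contains a single class")
        rng = np.random.default_rng(schedule.seed)
        lr = schedule.learning_rate
        best_val = np.inf
        best_weights: list[np.ndarray] | None = None
        epochs_since_best = 0
        history = []
        for epoch in range(1, schedule.max_epochs + 1):
            order = rng.permutation(len(X))
            for start in range(0, len(X), schedule.batch_size):
                idx = order[start : start + schedule.batch_size]
                self._step(X[idx], y[idx], lr)
            train_loss = self._bce_from_logits(self.predict_logits(X), y)
            val_loss = self._bce_from_logits(self.predict_logits(X_val), y_val)
            if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} (lr={lr:g}); aborting"
                )
            history.append((epoch, lr, train_loss, val_loss))
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = [w.copy() for w in self.weights] + [
                    b.copy() for b in self.biases
                ]
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best > 0 and epochs_since_best % schedule.lr_patience == 0:
                    lr *= 0.5
                if epochs_since_best >= schedule.es_patience:
                    break
        if best_weights is not None:
            k = len(self.weights)
            self.weights = best_weights[:k]
            self.biases = best_weights[k:]
        return pd.DataFrame(history, columns=["epoch", "lr", "train_loss", "val_loss"])
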