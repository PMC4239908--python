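"""Feedforward backpropagation network for the 3-D query → 9-D pose map.

A small fully-connected regression network with tanh hidden units and an
identity output layer, trained by seeded mini-batch gradient descent on the
mean-squared error.  Weights are initialised uniformly in ±1/√fan_in.  The
default architecture is a single hidden layer of 30 units; deeper stacks can
be configured through ``hidden``.  Inputs and outputs are z-scored
internally, and the forward pass is fully deterministic given the weights.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DataError

__all__ = ["BackpropMLP", "mlp_fit", "mlp_predict"]


class BackpropMLP(RegressorMixin, BaseEstimator):
    """Multilayer perceptron regressor trained with plain backpropagation.

    Parameters
    ----------
    hidden : sequence of int, default (30,)
        Hidden layer widths.
    epochs : int, default 300
        Passes over the training data.
    lr : float, default 1e-2
        Gradient-descent step size.
    batch_size : int, default 32
        Mini-batch size (shuffled each epoch with the seeded RNG).
    seed : int, default 0
        Seeds initialisation and batch shuffling; identical seed + data give
        identical weights.
    standardize : bool, default True
        Z-score inputs and outputs internally.
    """

    def __init__(self, hidden=(30,), epochs: int = 300, lr: float = 1e-2,
                 batch_size: int = 32, seed: int = 0, standardize: bool = True):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.standardize = standardize

    # -- core passes ------------------------------------------------------

    def _forward(self, X, weights, biases):
        """Forward pass; returns activations per layer (a[0] is the input)."""
        a = [X]
        for li, (W, b) in enumerate(zip(weights, biases)):
            z = a[-1] @ W + b
            a.append(np.tanh(z) if li < len(weights) - 1 else z)
        return a

    def _backward(self, a, Y, weights):
        """Gradients of the MSE loss 1/(n·m)·Σ‖ŷ−y‖² w.r.t. weights/biases."""
        n, m = Y.shape
        delta = 2.0 * (a[-1] - Y) / (n * m)
        gW, gb = [], []
        for li in range(len(weights) - 1, -1, -1):
            gW.append(a[li].T @ delta)
            gb.append(delta.sum(axis=0))
            if li > 0:
                delta = (delta @ weights[li].T) * (1.0 - a[li] ** 2)
        return gW[::-1], gb[::-1]

    def _loss(self, X, Y, weights, biases):
        out = self._forward(X, weights, biases)[-1]
        return float(np.mean((out - Y) ** 2))

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or len(X) != len(Y):
            raise DataError("X must be (n, d) and aligned with y")
        if len(X) < 10:
            raise DataError("need at least 10 training samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise DataError("training data contain non-finite values")
        if self.standardize:
            self.x_mean_, self.x_scale_ = X.mean(0), X.std(0)
            self.y_mean_, self.y_scale_ = Y.mean(0), Y.std(0)
            self.x_scale_ = np.where(self.x_scale_ == 0, 1.0, self.x_scale_)
            self.y_scale_ = np.where(self.y_scale_ == 0, 1.0, self.y_scale_)
        else:
            self.x_mean_ = np.zeros(X.shape[1]); self.x_scale_ = np.ones(X.shape[1])
            self.y_mean_ = np.zeros(Y.shape[1]); self.y_scale_ = np.ones(Y.shape[1])
        Xs = (X - self.x_mean_) / self.x_scale_
        Ys = (Y - self.y_mean_) / self.y_scale_

        sizes = [X.shape[1], *map(int, self.hidden), Y.shape[1]]
        rng = np.random.default_rng(self.seed)
        weights = [rng.uniform(-1, 1, (a, b)) / np.sqrt(a)
                   for a, b in zip(sizes[:-1], sizes[1:])]
        biases = [rng.uniform(-1, 1, b) / np.sqrt(a)
                  for a, b in zip(sizes[:-1], sizes[1:])]
        n = len(Xs)
        self.loss_curve_ = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                a = self._forward(Xs[idx], weights, biases)
                gW, gb = self._backward(a, Ys[idx], weights)
                for W, b, dW, db in zip(weights, biases, gW, gb):
                    W -= self.lr * dW
                    b -= self.lr * db
            loss = self._loss(Xs, Ys, weights, biases)
            if not np.isfinite(loss):
                raise DataError("training diverged (NaN loss); lower lr")
            self.loss_curve_.append(loss)
        self.weights_ = weights
        self.biases_ = biases
        self.layer_sizes_ = sizes
        self.n_features_in_ = sizes[0]
        self.n_outputs_ = sizes[-1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean_) / self.x_scale_
        out = self._forward(Xs, self.weights_, self.biases_)[-1]
        return out * self.y_scale_ + self.y_mean_

    # -- gradient-check hook ----------------------------------------------

    def numerical_gradient_error(self, X, Y, eps: float = 1e-6,
                                 seed: int = 0) -> float:
        """Max relative error of backprop vs central finite differences.

        Uses freshly initialised weights on standardized copies of the data;
        intended for verifying the analytic gradients on small networks.
        """
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        sizes = [X.shape[1], *map(int, self.hidden), Y.shape[1]]
        rng = np.random.default_rng(seed)
        weights = [rng.uniform(-1, 1, (a, b)) / np.sqrt(a)
                   for a, b in zip(sizes[:-1], sizes[1:])]
        biases = [rng.uniform(-1, 1, b) for a, b in zip(sizes[:-1], sizes[1:])]
        a = self._forward(X, weights, biases)
        gW, gb = self._backward(a, Y, weights)
        worst = 0.0
        for li, (W, dW) in enumerate(zip(weights, gW)):
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                ij = it.multi_index
                orig = W[ij]
                W[ij] = orig + eps
                lp = self._loss(X, Y, weights, biases)
                W[ij] = orig - eps
                lm = self._loss(X, Y, weights, biases)
                W[ij] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(dW[ij]), 1e-8)
                worst = max(worst, abs(num - dW[ij]) / denom)
        for li, (b, db) in enumerate(zip(biases, gb)):
            for j in range(b.size):
                orig = b[j]
                b[j] = orig + eps
                lp = self._loss(X, Y, weights, biases)
                b[j] = orig - eps
                lm = self._loss(X, Y, weights, biases)
                b[j] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(db[j]), 1e-8)
                worst = max(worst, abs(num - db[j]) / denom)
        return worst

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "weights_")
        return {
            "model": "nn",
            "params": {"hidden": list(map(int, self.hidden)),
                       "epochs": self.epochs, "lr": self.lr,
                       "batch_size": self.batch_size, "seed": self.seed,
                       "standardize": self.standardize},
            "x_mean": self.x_mean_.tolist(), "x_scale": self.x_scale_.tolist(),
            "y_mean": self.y_mean_.tolist(), "y_scale": self.y_scale_.tolist(),
            "weights": [W.tolist() for W in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BackpropMLP":
        p = doc["params"]
        model = cls(hidden=tuple(p["hidden"]), epochs=p["epochs"], lr=p["lr"],
                    batch_size=p["batch_size"], seed=p["seed"],
                    standardize=p["standardize"])
        model.x_mean_ = np.asarray(doc["x_mean"])
        model.x_scale_ = np.asarray(doc["x_scale"])
        model.y_mean_ = np.asarray(doc["y_mean"])
        model.y_scale_ = np.asarray(doc["y_scale"])
        model.weights_ = [np.asarray(W) for W in doc["weights"]]
        model.biases_ = [np.asarray(b) for b in doc["biases"]]
        model.layer_sizes_ = [model.weights_[0].shape[0]] + \
            [W.shape[1] for W in model.weights_]
        model.n_features_in_ = model.layer_sizes_[0]
        model.n_outputs_ = model.layer_sizes_[-1]
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BackpropMLP":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def mlp_fit(queries, targets, hidden=(30,), epochs: int = 300,
            lr: float = 1e-2, seed: int = 0, **kwargs) -> BackpropMLP:
    """Train the pose network on query/relative-pose series."""
    X = queries.as_matrix() if hasattr(queries, "as_matrix") else np.asarray(queries)
    Y = targets.as_matrix() if hasattr(targets, "as_matrix") else np.asarray(targets)
    model = BackpropMLP(hidden=hidden, epochs=epochs, lr=lr, seed=seed, **kwargs)
    return model.fit(X, Y)


def mlp_predict(model: BackpropMLP, x) -> np.ndarray:
    """Predict the 9-D relative pose for a single query 3-vector."""
    return model.predict(np.atleast_2d(x))[0]
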