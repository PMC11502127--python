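"""Extreme learning machine (ELM) for binary classification.

A single-hidden-layer feedforward network whose hidden weights and biases
are random and *fixed*: training solves only the linear output weights, in
closed form, against the {0,1} labels.  With hidden activations
H = g(X W + b), the output weights are the ridge-regularised least-squares
solution

    beta = (H' H + ridge * I)^-1 H' y,

so fitting is a single linear solve.  Scores are the clipped network
outputs; labels threshold at 0.5.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .preprocess import ExpressionMatrix

__all__ = ["ELMClassifier", "elm_fit", "elm_predict"]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer network with random fixed hidden weights.

    Parameters
    ----------
    n_hidden : int, default=100
        Hidden-layer width.
    activation : {'sigmoid', 'tanh'}, default='sigmoid'
    ridge : float, default=1e-6
        Tikhonov regulariser on the output-weight solve; with ridge=0 a
        singular system falls back to the pseudo-inverse.
    random_state : int, default=0
        Seeds the hidden weights/biases; fitting is deterministic given it.
    """

    def __init__(self, n_hidden: int = 100, activation: str = "sigmoid",
                 ridge: float = 1e-6, random_state: int = 0):
        self.n_hidden = n_hidden
        self.activation = activation
        self.ridge = ridge
        self.random_state = random_state

    def _hidden(self, X):
        act = _ACTIVATIONS[self.activation]
        return act(X @ self.input_weights_ + self.biases_)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        d = X.shape[1]
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(d, self.n_hidden))
        self.biases_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._hidden(X)
        t = (y == self.classes_[-1]).astype(float)
        A = H.T @ H + self.ridge * np.eye(self.n_hidden)
        try:
            self.output_weights_ = np.linalg.solve(A, H.T @ t)
        except np.linalg.LinAlgError:
            self.output_weights_ = np.linalg.pinv(H) @ t
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        X = validate_data(self, X, reset=False, dtype=float)
        return self._hidden(X) @ self.output_weights_

    def predict_proba(self, X):
        score = np.clip(self.decision_function(X), 0.0, 1.0)
        return np.column_stack([1.0 - score, score])

    def predict(self, X):
        score = self.predict_proba(X)[:, 1]
        idx = (score >= 0.5).astype(int)
        if len(self.classes_) == 1:
            idx[:] = 0
        return self.classes_[idx]


def elm_fit(train: ExpressionMatrix, n_hidden: int = 100,
            activation: str = "sigmoid", ridge: float = 1e-6,
            seed: int = 0) -> ELMClassifier:
    """Fit an ELM on an :class:`ExpressionMatrix`."""
    clf = ELMClassifier(n_hidden=n_hidden, activation=activation,
                        ridge=ridge, random_state=seed)
    return clf.fit(train.values, train.labels)


def elm_predict(model: ELMClassifier, X) -> np.ndarray:
    """Positive-class scores in [0, 1] for a matrix or ExpressionMatrix."""
    vals = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X)
    return model.predict_proba(vals)[:, 1]
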