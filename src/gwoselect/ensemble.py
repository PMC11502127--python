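"""Top-3 learner selection and voting / weighted-average ensembles.

The three base learners with the highest inner-validation accuracy form
the ensemble.  Two combination modes:

* majority voting — per sample, the label predicted by most members (the
  member count is kept odd so no tie is possible);
* weighted averaging — member positive-class scores combined with weights
  proportional to the members' validation accuracies; label 1 iff the
  combined score >= 0.5 (the boundary goes to class 1).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .cfs import FeatureMask
from .learners import LEARNER_ORDER, LearnerReport, train_base_learners
from .preprocess import ExpressionMatrix

__all__ = [
    "select_top_k",
    "majority_vote",
    "weighted_average",
    "TopKEnsembleClassifier",
]


def select_top_k(reports: list[LearnerReport], k: int = 3) -> list[LearnerReport]:
    """The k reports with highest validation accuracy, accuracy-descending;
    ties resolve to the canonical learner order."""
    if not 1 <= k <= len(reports):
        raise ValueError(f"k must lie in [1, {len(reports)}]")
    order = {name: i for i, name in enumerate(LEARNER_ORDER)}
    ranked = sorted(reports,
                    key=lambda r: (-r.validation_accuracy,
                                   order.get(r.name, len(order))))
    return ranked[:k]


def majority_vote(predictions) -> np.ndarray:
    """Row-wise majority label over an (n_samples, n_members) 0/1 matrix."""
    P = np.asarray(predictions, dtype=int)
    if P.ndim != 2:
        raise ValueError("predictions must be 2-D (samples x members)")
    if P.shape[1] % 2 == 0:
        raise ValueError("majority voting needs an odd number of members")
    return (P.sum(axis=1) * 2 > P.shape[1]).astype(int)


def weighted_average(scores, weights) -> np.ndarray:
    """Threshold the weighted mean of member scores at 0.5 (ties -> 1)."""
    S = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if S.ndim != 2 or w.shape != (S.shape[1],):
        raise ValueError("scores must be (samples x members) matching weights")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return (S @ w >= 0.5).astype(int)


class TopKEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Train the seven-learner roster, keep the top k, combine predictions.

    Feature selection is expected upstream (e.g. a ``CFSSelector`` →
    ``IGWOSelector`` → ``TopKEnsembleClassifier`` pipeline); this estimator
    uses every column it is given.

    Parameters
    ----------
    k : int, default=3
        Ensemble size (odd, so voting cannot tie).
    mode : {'voting', 'averaging'}, default='voting'
        Combination rule used by :meth:`predict`.
    val_fraction : float, default=0.2
        Inner-validation share of the training data used to rank learners.
    random_state : int, default=0

    Attributes
    ----------
    reports_ : list of LearnerReport (all seven, roster order)
    members_ : list of LearnerReport (the top k, accuracy-descending)
    weights_ : ndarray — members' validation accuracies normalised to sum 1
        (uniform if all validation accuracies are zero)
    """

    def __init__(self, k: int = 3, mode: str = "voting",
                 val_fraction: float = 0.2, random_state: int = 0):
        self.k = k
        self.mode = mode
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        if self.mode not in ("voting", "averaging"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.classes_ = np.unique(y)
        em = ExpressionMatrix(values=X, labels=y.astype(int))
        full = FeatureMask(np.ones(X.shape[1], dtype=bool))
        self.reports_ = train_base_learners(
            em, full, val_fraction=self.val_fraction, seed=self.random_state
        )
        self.members_ = select_top_k(self.reports_, self.k)
        accs = np.array([m.validation_accuracy for m in self.members_])
        self.weights_ = (accs / accs.sum() if accs.sum() > 0
                         else np.full(self.k, 1.0 / self.k))
        return self

    def member_labels(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        return np.column_stack([m.model.predict_labels(X)
                                for m in self.members_])

    def member_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        return np.column_stack([m.model.predict_scores(X)
                                for m in self.members_])

    def decision_function(self, X):
        X = validate_data(self, X, reset=False, dtype=float)
        return self.member_scores(X) @ self.weights_

    def predict_voting(self, X) -> np.ndarray:
        X = validate_data(self, X, reset=False, dtype=float)
        return majority_vote(self.member_labels(X))

    def predict_averaging(self, X) -> np.ndarray:
        X = validate_data(self, X, reset=False, dtype=float)
        return weighted_average(self.member_scores(X), self.weights_)

    def predict(self, X):
        if self.mode == "voting":
            return self.predict_voting(X)
        return self.predict_averaging(X)
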