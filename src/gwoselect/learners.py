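"""The seven base learners and their inner-validation accuracy reports.

Learner roster (fixed order, used for tie-breaking everywhere downstream):
LR, KNN, SVM, DT, ELM, MLP, AdaBoost.  Six delegate to scikit-learn; the
extreme learning machine is implemented in :mod:`gwoselect.elm`.  Each
learner is fitted on the masked genes of an inner training portion and
scored on a stratified inner validation split that the fit never sees —
the validation accuracies later pick the top-3 ensemble members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cfs import FeatureMask
from .elm import ELMClassifier
from .preprocess import ExpressionMatrix

__all__ = [
    "LEARNER_ORDER",
    "FittedModel",
    "LearnerReport",
    "make_learner",
    "train_base_learners",
]

#: Canonical learner order; ties in accuracy rankings resolve to it.
LEARNER_ORDER = ("LR", "KNN", "SVM", "DT", "ELM", "MLP", "AdaBoost")


def make_learner(name: str, seed: int = 0, **overrides):
    """Instantiate a base learner by roster name with its default settings."""
    defaults = {
        "LR": lambda: LogisticRegression(max_iter=2000),  # L2 by default
        "KNN": lambda: KNeighborsClassifier(n_neighbors=5),
        "SVM": lambda: SVC(kernel="rbf", C=1.0, random_state=seed),
        "DT": lambda: DecisionTreeClassifier(criterion="gini",
                                             random_state=seed),
        "ELM": lambda: ELMClassifier(n_hidden=100, activation="sigmoid",
                                     ridge=1e-6, random_state=seed),
        # full-batch lbfgs: stable at the tens-of-samples regime where
        # minibatch training with a tiny early-stopping split is erratic
        "MLP": lambda: MLPClassifier(hidden_layer_sizes=(100,),
                                     solver="lbfgs", alpha=1e-3,
                                     max_iter=1000, random_state=seed),
        "AdaBoost": lambda: AdaBoostClassifier(n_estimators=50,
                                               random_state=seed),
    }
    if name not in defaults:
        raise ValueError(f"unknown learner {name!r}")
    est = defaults[name]()
    if overrides:
        est.set_params(**overrides)
    return est


@dataclass
class FittedModel:
    """A fitted base learner restricted to a fixed gene subset.

    Predictions depend only on the masked columns: inputs are sliced to
    ``feature_idx`` before reaching the underlying estimator, so changes in
    non-selected genes cannot affect the output.
    """

    name: str
    estimator: object
    feature_idx: np.ndarray
    seed: int = 0

    def _slice(self, X):
        vals = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X)
        return vals[:, self.feature_idx]

    def predict_labels(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._slice(X)), dtype=int)

    def predict_scores(self, X) -> np.ndarray:
        """Positive-class score in [0,1]; indicator {0,1} for learners
        without native probabilities (SVM)."""
        Xs = self._slice(X)
        if hasattr(self.estimator, "predict_proba"):
            pos = list(self.estimator.classes_).index(1)
            return np.clip(self.estimator.predict_proba(Xs)[:, pos], 0.0, 1.0)
        return np.asarray(self.estimator.predict(Xs), dtype=float)


@dataclass
class LearnerReport:
    """A fitted model plus its accuracy on the inner validation split."""

    name: str
    validation_accuracy: float
    model: FittedModel = field(repr=False, default=None)


def train_base_learners(train: ExpressionMatrix, mask: FeatureMask,
                        val_fraction: float = 0.2,
                        seed: int = 0) -> list[LearnerReport]:
    """Fit all seven learners on masked genes; report validation accuracy.

    The training matrix is split once (stratified) into an inner-fit and an
    inner-validation portion; every learner fits on the former and is
    scored on the latter, so ranking never touches held-out test data.
    """
    idx = mask.indices if isinstance(mask, FeatureMask) else np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("feature mask is empty")
    if train.labels is None or len(np.unique(train.labels)) < 2:
        raise ValueError("training matrix must contain both classes")
    rows = np.arange(train.n_samples)
    fit_rows, val_rows = train_test_split(
        rows, test_size=val_fraction, stratify=train.labels, random_state=seed
    )
    Xfit = train.values[np.sort(fit_rows)][:, idx]
    yfit = train.labels[np.sort(fit_rows)]
    Xval = train.values[np.sort(val_rows)][:, idx]
    yval = train.labels[np.sort(val_rows)]

    reports = []
    for name in LEARNER_ORDER:
        est = make_learner(name, seed=seed)
        try:
            est.fit(Xfit, yfit)
        except Exception as exc:  # noqa: BLE001 - re-raise with learner name
            raise RuntimeError(f"learner {name} failed to fit: {exc}") from exc
        acc = float(np.mean(est.predict(Xval) == yval))
        fitted = FittedModel(name=name, estimator=est, feature_idx=idx,
                             seed=seed)
        reports.append(LearnerReport(name=name, validation_accuracy=acc,
                                     model=fitted))
    return reports
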