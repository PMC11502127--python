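"""Binary IGWO wrapper for feature-subset optimisation.

The optimiser runs in a continuous box [-4, 4]^d, one dimension per
candidate gene; a position is mapped to a feature mask through the sigmoid
transfer function (bit on iff S(z) >= 0.5, i.e. z >= 0), and scored by a
wrapper objective that balances classification error against subset size:

    fitness(mask) = w * (1 - cv_accuracy(mask)) + (1 - w) * |mask| / d

with cv_accuracy the stratified k-fold cross-validated accuracy of a
5-nearest-neighbour evaluator restricted to the masked genes.  The error
weight w (``alpha_weight``, default 0.99) keeps accuracy dominant while
still preferring smaller subsets among equally accurate ones.  Lower
fitness is better.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .cfs import FeatureMask
from .igwo import igwo_minimize
from .preprocess import ExpressionMatrix

__all__ = [
    "sigmoid_binarize",
    "KnnCvFitness",
    "feature_fitness",
    "IGWOSelector",
    "igwo_feature_select",
]

#: Continuous search box for the binary wrapper; the sigmoid spans
#: (0.018, 0.982) over [-4, 4], so both bit values stay reachable.
POSITION_BOUNDS = (-4.0, 4.0)


def sigmoid_binarize(position) -> np.ndarray:
    """Map a continuous position to a boolean mask: bit_j = (z_j > 0).

    An all-zero mask is repaired by switching on the bit with the largest
    z_j (lowest index among ties), so the mask is never empty.
    """
    z = np.asarray(position, dtype=float)
    bits = z > 0.0
    if not bits.any():
        bits[int(np.argmax(z))] = True
    return bits


class KnnCvFitness:
    """Wrapper objective: weighted CV error of 5-NN plus a size penalty.

    Folds are fixed at construction (stratified, seeded shuffle), so the
    objective is deterministic across calls; the k-NN evaluation is a
    vectorised Euclidean-distance majority vote, cheap enough for the
    thousands of evaluations an IGWO run makes.
    """

    def __init__(self, X, y, alpha_weight: float = 0.99, cv_folds: int = 5,
                 seed: int = 0, n_neighbors: int = 5):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if not 0.0 < alpha_weight < 1.0:
            raise ValueError("alpha_weight must lie in (0, 1)")
        self.alpha_weight = alpha_weight
        self.n_genes = self.X.shape[1]
        min_class = np.bincount(self.y).min()
        folds = max(2, min(cv_folds, int(min_class)))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        self.folds = list(skf.split(self.X, self.y))
        self.k = n_neighbors

    def cv_accuracy(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        Xm = self.X[:, mask]
        correct = 0
        for tr, te in self.folds:
            D = cdist(Xm[te], Xm[tr], "sqeuclidean")
            k = min(self.k, len(tr))
            nn = np.argpartition(D, k - 1, axis=1)[:, :k]
            votes = self.y[tr][nn].mean(axis=1)
            pred = (votes >= 0.5).astype(int)
            correct += int((pred == self.y[te]).sum())
        return correct / len(self.y)

    def __call__(self, mask) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("fitness of an empty mask is undefined")
        acc = self.cv_accuracy(mask)
        size_frac = mask.sum() / self.n_genes
        return self.alpha_weight * (1.0 - acc) + (1 - self.alpha_weight) * size_frac


def feature_fitness(mask: FeatureMask | np.ndarray, train: ExpressionMatrix,
                    alpha_weight: float = 0.99, cv_folds: int = 5,
                    seed: int = 0) -> float:
    """Wrapper fitness of one mask on a training matrix (lower is better)."""
    bits = mask.included if isinstance(mask, FeatureMask) else mask
    fn = KnnCvFitness(train.values, train.labels, alpha_weight=alpha_weight,
                      cv_folds=cv_folds, seed=seed)
    return fn(bits)


class IGWOSelector(SelectorMixin, BaseEstimator):
    """IGWO-driven wrapper feature selector over the columns of X.

    Typically chained after :class:`~gwoselect.cfs.CFSSelector` in a
    pipeline so the optimisation dimension is the (small) CFS candidate set
    rather than the full gene count.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
    fitness_ : float
        Wrapper objective value of the selected mask.
    trace_ : ndarray of shape (max_iter,)
        Global-best fitness per iteration (non-increasing).
    """

    def __init__(self, n_wolves: int = 30, max_iter: int = 100,
                 alpha_weight: float = 0.99, cv_folds: int = 5,
                 chaotic_map: str = "logistic", random_state: int = 0):
        self.n_wolves = n_wolves
        self.max_iter = max_iter
        self.alpha_weight = alpha_weight
        self.cv_folds = cv_folds
        self.chaotic_map = chaotic_map
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        dim = X.shape[1]
        objective = KnnCvFitness(X, y, alpha_weight=self.alpha_weight,
                                 cv_folds=self.cv_folds,
                                 seed=self.random_state)
        best_pos, best_fit, trace = igwo_minimize(
            lambda z: objective(sigmoid_binarize(z)),
            dim=dim, bounds=POSITION_BOUNDS, n_wolves=self.n_wolves,
            max_iter=self.max_iter, map_name=self.chaotic_map,
            seed=self.random_state,
        )
        self.support_ = sigmoid_binarize(best_pos)
        self.fitness_ = float(best_fit)
        self.trace_ = trace
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def igwo_feature_select(train: ExpressionMatrix, candidate_mask: FeatureMask,
                        n_wolves: int = 30, max_iter: int = 100,
                        alpha_weight: float = 0.99, cv_folds: int = 5,
                        chaotic_map: str = "logistic",
                        seed: int = 0) -> FeatureMask:
    """Refine a CFS candidate mask by IGWO; the result is a subset of it.

    The optimiser's bits index genes *within* the candidate set; the
    returned mask is mapped back to full gene coordinates.
    """
    cand_idx = candidate_mask.indices
    if cand_idx.size == 0:
        raise ValueError("candidate mask is empty")
    if cand_idx.size == 1:
        return FeatureMask(candidate_mask.included.copy())
    sel = IGWOSelector(n_wolves=n_wolves, max_iter=max_iter,
                       alpha_weight=alpha_weight, cv_folds=cv_folds,
                       chaotic_map=chaotic_map, random_state=seed)
    sel.fit(train.values[:, cand_idx], train.labels)
    mask = FeatureMask.from_indices(cand_idx[sel.support_], train.n_genes)
    mask.merit = None
    mask.fitness = sel.fitness_
    mask.trace = sel.trace_
    return mask
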