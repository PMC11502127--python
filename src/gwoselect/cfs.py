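"""Correlation-based feature selection (CFS).

A feature subset S of size i is scored by the merit statistic

    M(S) = i * mu_ic / sqrt(i + i*(i-1) * mu_ii)

where mu_ic is the mean absolute Pearson correlation between the features in
S and the class label (point-biserial: the {0,1} labels are treated
numerically), and mu_ii the mean absolute pairwise correlation within S.
High class-relevance raises the merit; redundancy between features lowers
it.  Selection is a deterministic greedy forward search over genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .preprocess import ExpressionMatrix

__all__ = [
    "FeatureMask",
    "MeritScore",
    "CFSSelector",
    "pearson_correlation",
    "merit_score",
    "cfs_select",
]


@dataclass
class FeatureMask:
    """Boolean inclusion vector over genes — the unit of feature selection."""

    included: np.ndarray
    merit: float | None = None

    def __post_init__(self):
        self.included = np.asarray(self.included, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.included.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.included)

    @classmethod
    def from_indices(cls, idx, n_genes: int, merit: float | None = None):
        inc = np.zeros(n_genes, dtype=bool)
        inc[np.asarray(idx, dtype=int)] = True
        return cls(inc, merit)

    def gene_ids(self, X: ExpressionMatrix) -> list:
        return [X.gene_ids[i] for i in self.indices]

    def to_text(self, path, X: ExpressionMatrix) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.gene_ids(X)) + "\n")

    def to_json(self, path, X: ExpressionMatrix) -> None:
        with open(path, "w") as fh:
            json.dump({"gene_ids": self.gene_ids(X), "merit": self.merit},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class MeritScore:
    """Merit of a feature subset and its two correlation components."""

    n_features: int
    avg_feature_class_corr: float
    avg_feature_feature_corr: float

    @property
    def merit(self) -> float:
        i = self.n_features
        denom = i + i * (i - 1) * self.avg_feature_feature_corr
        if denom <= 0:
            return 0.0
        return i * self.avg_feature_class_corr / np.sqrt(denom)


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation; 0 if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("correlation needs at least 2 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0.0:
        return 0.0
    return float(np.clip((dx @ dy) / denom, -1.0, 1.0))


def _zscore_columns(V: np.ndarray) -> np.ndarray:
    """Population z-scores per column; constant columns become all-zero,
    so any correlation involving them is 0 by convention."""
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    sd_safe = np.where(sd < 1e-15, 1.0, sd)
    Z = (V - mu) / sd_safe
    Z[:, sd < 1e-15] = 0.0
    return Z


def merit_score(X: ExpressionMatrix, subset: FeatureMask) -> MeritScore:
    """Merit of the genes flagged in ``subset`` against ``X.labels``."""
    idx = subset.indices
    if idx.size == 0:
        raise ValueError("merit_score requires a non-empty subset")
    if X.labels is None:
        raise ValueError("merit_score requires labels")
    y = X.labels.astype(float)
    genes = [X.values[:, j] for j in idx]
    mu_ic = float(np.mean([abs(pearson_correlation(g, y)) for g in genes]))
    if idx.size == 1:
        mu_ii = 0.0
    else:
        pair = [abs(pearson_correlation(genes[a], genes[b]))
                for a in range(len(genes)) for b in range(a + 1, len(genes))]
        mu_ii = float(np.mean(pair))
    return MeritScore(int(idx.size), mu_ic, mu_ii)


class CFSSelector(SelectorMixin, BaseEstimator):
    """Greedy forward merit-maximising feature selector.

    Starting from the empty set, repeatedly adds the gene that maximises the
    merit of the augmented subset; stops after ``patience`` consecutive
    additions without improving the best merit seen, or at ``max_features``.
    Returns the subset at the best merit.  Deterministic; merit ties break
    toward the lower gene index.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Selected-gene mask.
    merit_ : float
        Merit of the selected subset.
    order_ : list of int
        Genes in the order the greedy search added them (may extend past the
        returned subset by up to ``patience`` unhelpful additions).
    """

    def __init__(self, max_features: int = 50, patience: int = 5):
        self.max_features = max_features
        self.patience = patience

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        n, p = X.shape
        Z = _zscore_columns(X) / np.sqrt(n)  # columns have unit L2 norm (or 0)
        zy_col = _zscore_columns(y.reshape(-1, 1).astype(float)) / np.sqrt(n)
        if not np.any(Z.any(axis=0)):
            raise ValueError("all genes are constant; nothing to select")

        class_corr = np.abs(Z.T @ zy_col[:, 0])          # |r(gene, label)|
        sum_abs_ff = np.zeros(p)       # Sum over selected s of |r(gene, s)|
        selected: list[int] = []
        sum_class = 0.0                # Sum of |r| class corr over selected
        sum_pairs = 0.0                # Sum of |r| over selected pairs
        best_merit = -np.inf
        best_k = 0
        stall = 0

        while len(selected) < min(self.max_features, p):
            k = len(selected)
            i = k + 1
            mu_ic = (sum_class + class_corr) / i
            n_pairs = i * (i - 1) / 2
            mu_ii = (sum_pairs + sum_abs_ff) / n_pairs if n_pairs else 0.0
            denom = i + i * (i - 1) * mu_ii
            merits = i * mu_ic / np.sqrt(denom)
            if selected:
                merits[np.asarray(selected)] = -np.inf
            j = int(np.argmax(merits))  # first max -> lowest-index tie-break
            m = float(merits[j])
            selected.append(j)
            sum_class += class_corr[j]
            sum_pairs += sum_abs_ff[j]
            sum_abs_ff += np.abs(Z.T @ Z[:, j])
            sum_abs_ff[j] = 0.0
            if m > best_merit + 1e-12:
                best_merit = m
                best_k = len(selected)
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break

        support = np.zeros(p, dtype=bool)
        support[selected[:best_k]] = True
        self.support_ = support
        self.merit_ = best_merit
        self.order_ = selected
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def cfs_select(X: ExpressionMatrix, max_features: int = 50,
               patience: int = 5) -> FeatureMask:
    """Greedy CFS over an :class:`ExpressionMatrix`; see :class:`CFSSelector`."""
    sel = CFSSelector(max_features=max_features, patience=patience)
    sel.fit(X.values, X.labels)
    return FeatureMask(sel.support_, merit=sel.merit_)
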