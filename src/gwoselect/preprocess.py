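"""Loading, normalisation and splitting of expression matrices.

An :class:`ExpressionMatrix` is the package's container for a samples x genes
numeric matrix with binary phenotype labels (1 = disease/positive class,
0 = normal).  Normalisation is per-gene standard scaling (zero mean, unit
population standard deviation); the train/test split is stratified by label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "ExpressionMatrix",
    "SplitPair",
    "StandardScalerEM",
    "load_matrix",
    "standard_scale",
    "stratified_split",
]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression matrix with sample/gene IDs and binary labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression values, any units; no missing entries allowed.
    sample_ids : list of str
    gene_ids : list of str
        Must be unique.
    labels : ndarray of shape (n_samples,)
        Integer labels in {0, 1}; 1 is the positive (disease) class.
    """

    values: np.ndarray
    sample_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    labels: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n, p = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"g{j}" for j in range(p)]
        self.sample_ids = list(map(str, self.sample_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match n_samples")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match n_genes")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match n_samples")
            uniq = set(np.unique(self.labels).tolist())
            if not uniq <= {0, 1}:
                raise ValueError("labels must be binary (0/1)")
            self.labels = self.labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else self.labels[idx],
        )

    def subset_genes(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            values=self.values[:, mask],
            sample_ids=list(self.sample_ids),
            gene_ids=[g for g, m in zip(self.gene_ids, mask) if m],
            labels=self.labels,
        )

    def to_csv(self, path, label_column: str = "label") -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        if self.labels is not None:
            df[label_column] = self.labels
        df.to_csv(path, index_label="sample_id")


@dataclass
class SplitPair:
    """A stratified train/test partition of a parent :class:`ExpressionMatrix`."""

    train: ExpressionMatrix
    test: ExpressionMatrix
    ratio: float
    seed: int


class StandardScalerEM:
    """Per-gene standard scaler (population sd); constant genes map to zeros.

    Statistics are estimated by :meth:`fit` (on training data only, in a
    leak-free pipeline) and re-applied to any matrix by :meth:`transform`.
    """

    def fit(self, X: ExpressionMatrix) -> "StandardScalerEM":
        if X.n_samples == 0 or X.n_genes == 0:
            raise ValueError("cannot scale an empty matrix")
        self.mean_ = X.values.mean(axis=0)
        self.scale_ = X.values.std(axis=0)  # population (ddof=0)
        self.constant_ = self.scale_ < 1e-12
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        scale = np.where(self.constant_, 1.0, self.scale_)
        vals = (X.values - self.mean_) / scale
        vals[:, self.constant_] = 0.0
        return replace(X, values=vals)

    def fit_transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        return self.fit(X).transform(X)


def load_matrix(path, label_column_or_file="label", *, sep=None,
                transpose: bool = False) -> ExpressionMatrix:
    """Load a delimited expression matrix with binary labels.

    Layout: header row of gene IDs, first column of sample IDs, one row per
    sample.  Labels come either from a named column of the matrix file or
    from a two-column companion file (sample_id, label).  ``transpose=True``
    accepts the genes x samples orientation and transposes on read.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T

    labels = None
    if label_column_or_file in df.columns:
        labels = df[label_column_or_file]
        df = df.drop(columns=[label_column_or_file])
    else:
        lab = pd.read_csv(label_column_or_file, sep=None, engine="python",
                          index_col=0).iloc[:, 0]
        labels = lab.reindex(df.index)
        if labels.isna().any():
            missing = labels.index[labels.isna()][0]
            raise ValueError(f"label file has no entry for sample {missing!r}")

    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"missing value at sample {row!r}, gene {col!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[bad.isna()][0]
                raise ValueError(
                    f"non-numeric value at sample {row!r}, gene {col!r}"
                ) from None
        raise

    uniq = set(pd.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary (0/1); got values {sorted(uniq)}")

    return ExpressionMatrix(
        values=values,
        sample_ids=list(df.index.astype(str)),
        gene_ids=list(df.columns.astype(str)),
        labels=np.asarray(labels, dtype=int),
    )


def standard_scale(X: ExpressionMatrix, *, test: ExpressionMatrix | None = None):
    """Scale genes to mean 0 / population sd 1; constant genes become zeros.

    With ``test`` given, statistics come from ``X`` only and are applied to
    both, returning ``(scaled_train, scaled_test)``.
    """
    scaler = StandardScalerEM().fit(X)
    if test is not None:
        return scaler.transform(X), scaler.transform(test)
    return scaler.transform(X)


def stratified_split(X: ExpressionMatrix, ratio: float = 0.8,
                     seed: int = 0) -> SplitPair:
    """Stratified train/test split; ``ratio`` is the training fraction."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if X.labels is None:
        raise ValueError("stratified_split requires labels")
    counts = np.bincount(X.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            "each class needs at least 2 samples for a stratified split"
        )
    n_test = X.n_samples - int(round(ratio * X.n_samples))
    if n_test < 1 or n_test >= X.n_samples:
        raise ValueError("ratio produces an empty train or test partition")
    idx = np.arange(X.n_samples)
    tr, te = train_test_split(
        idx, test_size=n_test, stratify=X.labels, random_state=seed
    )
    tr, te = np.sort(tr), np.sort(te)
    return SplitPair(train=X.subset_samples(tr), test=X.subset_samples(te),
                     ratio=ratio, seed=seed)
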