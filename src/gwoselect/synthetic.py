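"""Synthetic microarray-like data with planted ground truth.

Emulates the shape regime of public cancer microarray panels — tens of
samples, hundreds to ~12,500 genes, binary tumor/normal labels — with a
known set of class-informative genes so every pipeline stage can be tested
for recovery without external downloads.

Model: a two-class equal-variance Gaussian.  Informative genes are
N(0, 1) in class 0 and N(delta, 1) in class 1; redundant genes are noisy
copies (parent + N(0, noise_sd)) of informative genes, exercising the
inter-feature-redundancy penalty of the CFS merit; all remaining genes are
N(0, 1) independent of the labels.  Gene roles are assigned to randomly
permuted column positions.  Class counts are exact (round(n * balance)),
so both classes are always present.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .cfs import FeatureMask
from .preprocess import ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "make_microarray",
           "recovery_score"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a small high-signal panel."""

    n_samples: int = 100
    n_genes: int = 500
    n_informative: int = 20
    n_redundant: int = 10
    effect_size: float = 2.0   # class-mean shift, in within-class sd units
    noise_sd: float = 0.5      # sd of the perturbation on redundant copies
    class_balance: float = 0.5  # fraction of samples in class 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative + self.n_redundant > self.n_genes:
            raise ValueError("informative + redundant genes exceed n_genes")
        if self.n_samples < 8:
            raise ValueError("need at least 8 samples")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant genes need informative parents")


@dataclass
class SyntheticTruth:
    """A generated matrix plus the planted-gene bookkeeping."""

    matrix: ExpressionMatrix
    informative_idx: np.ndarray
    redundant_idx: np.ndarray
    redundant_parent: dict        # redundant gene index -> parent index
    config: SyntheticConfig

    def truth_json(self, path) -> None:
        payload = {
            "informative_idx": sorted(int(i) for i in self.informative_idx),
            "redundant_idx": sorted(int(i) for i in self.redundant_idx),
            "redundant_parent": {str(k): int(v)
                                 for k, v in sorted(self.redundant_parent.items())},
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def make_microarray(cfg: SyntheticConfig) -> SyntheticTruth:
    """Generate a labelled matrix with planted informative/redundant genes."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n, p = cfg.n_samples, cfg.n_genes
    n_pos = int(round(cfg.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)  # both classes present
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1

    roles = rng.permutation(p)
    inf_idx = np.sort(roles[:cfg.n_informative])
    red_idx = np.sort(roles[cfg.n_informative:cfg.n_informative + cfg.n_redundant])

    values = rng.standard_normal((n, p))
    values[np.ix_(labels == 1, inf_idx)] += cfg.effect_size

    parent = {}
    if cfg.n_redundant:
        parents = inf_idx[rng.integers(0, len(inf_idx), size=len(red_idx))]
        for r, q in zip(red_idx, parents):
            values[:, r] = values[:, q] + cfg.noise_sd * rng.standard_normal(n)
            parent[int(r)] = int(q)

    em = ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i:04d}" for i in range(n)],
        gene_ids=[f"g{j:05d}" for j in range(p)],
        labels=labels,
    )
    return SyntheticTruth(matrix=em, informative_idx=inf_idx,
                          redundant_idx=red_idx, redundant_parent=parent,
                          config=cfg)


def recovery_score(selected: FeatureMask | np.ndarray,
                   truth: SyntheticTruth) -> float:
    """Fraction of informative genes recovered by a selection mask.

    A redundant copy counts as recovering its parent when the parent
    itself is absent from the mask.
    """
    bits = selected.included if isinstance(selected, FeatureMask) else \
        np.asarray(selected, dtype=bool)
    if truth.informative_idx.size == 0:
        return 0.0
    recovered = set(int(i) for i in truth.informative_idx if bits[i])
    for r, q in truth.redundant_parent.items():
        if bits[int(r)]:
            recovered.add(int(q))
    return len(recovered) / len(truth.informative_idx)
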