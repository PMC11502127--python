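import numpy as np
import pytest

from gwoselect.preprocess import ExpressionMatrix
from gwoselect.synthetic import SyntheticConfig, make_microarray


@pytest.fixture
def toy_matrix():
    """4 samples x 3 genes with labels [1, 1, 0, 0]."""
    values = np.array([
        [5.0, 1.0, 0.2],
        [4.5, 2.0, 0.1],
        [1.0, 3.0, 0.3],
        [0.5, 4.0, 0.4],
    ])
    return ExpressionMatrix(values=values,
                            sample_ids=["a", "b", "c", "d"],
                            gene_ids=["g1", "g2", "g3"],
                            labels=np.array([1, 1, 0, 0]))


@pytest.fixture
def separable_matrix():
    """Linearly separable two-class data: two strongly shifted genes."""
    rng = np.random.default_rng(42)
    n = 60
    labels = np.array([0, 1] * (n // 2))
    values = rng.standard_normal((n, 10)) * 0.2
    values[labels == 1, 0] += 5.0
    values[labels == 1, 1] -= 5.0
    from gwoselect.preprocess import standard_scale
    return standard_scale(ExpressionMatrix(values=values, labels=labels))


@pytest.fixture
def planted_truth():
    """Small planted-signal panel (high signal, quick to run)."""
    return make_microarray(SyntheticConfig(
        n_samples=100, n_genes=120, n_informative=8, n_redundant=4,
        effect_size=2.0, seed=11))
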