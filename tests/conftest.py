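import numpy as np
import pytest

from msisig.io_formats import ExpressionMatrix
from msisig.simulate import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 samples x 2 genes, hand-written values."""
    return ExpressionMatrix(
        ["s1", "s2", "s3"],
        ["gA", "gB"],
        np.array([[0.1, -0.2], [0.3, 0.4], [-0.5, 0.6]]),
        {"scale": "log2"},
    )


@pytest.fixture
def default_config():
    return GeneratorConfig()


def two_class_matrix(rng, n_per_class=20, n_genes=100, n_informative=10, effect=2.0):
    """A small labelled matrix with a known informative-gene block."""
    n = 2 * n_per_class
    values = rng.normal(0.0, 1.0, size=(n, n_genes))
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    values[labels == 1, :n_informative] += effect
    genes = [f"G{j:04d}" for j in range(1, n_genes + 1)]
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    return ExpressionMatrix(samples, genes, values), labels, genes[:n_informative]
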