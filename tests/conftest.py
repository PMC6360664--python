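import numpy as np
import pandas as pd
import pytest

from stemsig import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, annotations=None):
    """Build an ExpressionMatrix from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    genes = gene_ids or [f"G{i + 1}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"S{j + 1}" for j in range(arr.shape[1])]
    values = pd.DataFrame(arr, index=genes, columns=samples)
    ann = None
    if annotations is not None:
        ann = pd.DataFrame(annotations, index=samples)
    return ExpressionMatrix(values, ann)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with distinct, untied values."""
    return make_matrix(
        [
            [1.0, 2.0, 3.0, 4.0],
            [8.0, 6.0, 4.0, 2.0],
            [0.5, 0.1, 0.9, 0.3],
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
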