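import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import txplore as tx


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: 500 genes, 3 groups x 4 samples, planted
    markers, DE genes, and enriched sets."""
    return tx.generate_dataset(tx.SyntheticSpec(seed=7, n_null_sets=3))


@pytest.fixture(scope="session")
def cpm_matrix(bundle):
    return tx.cpm(bundle.matrix)


@pytest.fixture(scope="session")
def log_matrix(cpm_matrix):
    return tx.log_transform(cpm_matrix, 1.0)


@pytest.fixture
def tiny_matrix():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["g1", "g2"],
        columns=["s1", "s2", "s3"],
    )
    return tx.ExpressionMatrix(frame, "counts")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
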