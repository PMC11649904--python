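import logging

import numpy as np
import pandas as pd
import pytest

from modfuse.core_io import Config, FeatureMatrix, PhenotypeTable

logging.getLogger("modfuse").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_matrix(rng):
    """120 samples x 50 features, first 5 features shifted in cases."""
    n, p = 120, 50
    y = np.zeros(n, dtype=int)
    y[:30] = 1
    X = rng.standard_normal((n, p))
    X[:, :5] += y[:, None] * 1.0
    ids = [f"S{i:03d}" for i in range(n)]
    feats = [f"f{j:03d}" for j in range(p)]
    matrix = FeatureMatrix(
        "transcriptomic", pd.DataFrame(X, index=ids, columns=feats)
    )
    labels = PhenotypeTable(
        pd.DataFrame({"label": y}, index=pd.Index(ids, name="sample_id"))
    )
    return matrix, labels


@pytest.fixture
def default_config():
    return Config()
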