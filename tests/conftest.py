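import numpy as np
import pytest

from hyperjnmf import (
    FactorizationParams,
    SyntheticConfig,
    build_cross_adjacency,
    build_knn_hypergraph,
    generate,
    hypergraph_laplacian,
    standardize_columns,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pair(rng):
    """Two standardized 12-sample modalities (8 and 6 features)."""
    x1 = standardize_columns(rng.uniform(0.1, 1.0, size=(12, 8)))
    x2 = standardize_columns(rng.uniform(0.1, 1.0, size=(12, 6)))
    return x1, x2


@pytest.fixture
def small_dataset():
    """Noisy synthetic pair with labels at modest size."""
    return generate(SyntheticConfig(n_samples=20, p1=15, p2=12, K=5, noise_level=1.0, seed=7))


@pytest.fixture
def regularized_inputs(small_dataset):
    """Standardized matrices plus adjacency and both hypergraph Laplacians."""
    ds = small_dataset
    x1 = standardize_columns(ds.x1)
    x2 = standardize_columns(ds.x2)
    a = build_cross_adjacency(x1, x2, threshold=0.5)
    b1 = hypergraph_laplacian(build_knn_hypergraph(x1, 4))
    b2 = hypergraph_laplacian(build_knn_hypergraph(x2, 4))
    return ds, x1, x2, a, b1, b2


@pytest.fixture
def mixed_params():
    return FactorizationParams(
        K=5,
        alpha=0.01,
        lambda1=0.01,
        lambda2=0.01,
        beta1=0.01,
        beta2=0.01,
        gamma1=0.01,
        gamma2=0.01,
        max_iter=100,
    )
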