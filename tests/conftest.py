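import numpy as np
import pytest

import hcsim as H


@pytest.fixture(scope="session")
def planted():
    """The standard two-level fixture: 3 parents, 11 children, 0.7 signal."""
    X, truth = H.generate_hierarchical_blocks(H.default_block_spec(), seed=1)
    return X, truth


@pytest.fixture(scope="session")
def fitted_model(planted):
    """k=1, g=2 model on the planted fixture (the recovery configuration)."""
    X, _ = planted
    return H.hcr_fit(X, f_E=0.9, k=1, g_max=2, seed=1)


@pytest.fixture(scope="session")
def small_model():
    """A tiny fitted model for round-trip and accounting tests."""
    spec = H.BlockSpec(
        parent_blocks=[
            H.ParentSpec(0.5, [H.ChildSpec(5, 0.3), H.ChildSpec(5, 0.3)]),
            H.ParentSpec(0.5, [H.ChildSpec(5, 0.3), H.ChildSpec(5, 0.3)]),
        ],
        n_noise_variables=0,
        n_samples=50,
    )
    X, truth = H.generate_hierarchical_blocks(spec, seed=3)
    model = H.fit_decomposition(X, [truth.level1, truth.level2], k=2)
    return X, model


def rng(seed=0):
    return np.random.default_rng(seed)
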