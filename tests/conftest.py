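import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_fps(rng, n, m, density=0.2):
    """Random binary fingerprint matrix with no all-zero rows."""
    X = (rng.random((n, m)) < density).astype(np.uint8)
    for i in range(n):  # avoid degenerate all-zero fingerprints
        if X[i].sum() == 0:
            X[i, rng.integers(m)] = 1
    return X
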