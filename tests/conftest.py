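import numpy as np
import pytest

import substmat as sm


@pytest.fixture(scope="session")
def b62():
    return sm.load_standard("BLOSUM62")


@pytest.fixture(scope="session")
def standard_matrices():
    return {name: sm.load_standard(name) for name in sm.STANDARD_MATRICES}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_matrix(rng, name="rand", integer=True, low=-6, high=12):
    """A random symmetric matrix over the canonical alphabet."""
    n = len(sm.CANONICAL_ALPHABET)
    raw = rng.integers(low, high, size=(n, n)) if integer else rng.normal(0, 3, (n, n))
    scores = np.triu(raw) + np.triu(raw, 1).T
    return sm.SubstitutionMatrix(name=name, scores=scores.astype(float))
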