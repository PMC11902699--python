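import numpy as np
import pytest

import mtal


@pytest.fixture(scope="session")
def ku_small():
    """A reduced high-congruence benchmark for fast loop/model tests."""
    return mtal.ku_like(n=600, seed=11)


@pytest.fixture(scope="session")
def ku_full():
    """The default high-congruence benchmark (n=3000)."""
    return mtal.ku_like(n=3000, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_prob_rows(rng, m, c):
    """Random probability rows via normalised exponentials (always valid)."""
    raw = rng.exponential(size=(m, c))
    return raw / raw.sum(axis=1, keepdims=True)
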