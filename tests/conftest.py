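import numpy as np
import pytest

from phylodiff.reversible_model import ReversibleParams
from phylodiff.simulate import random_reversible_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_params(n: int, rng: np.random.Generator) -> ReversibleParams:
    return random_reversible_params(n, rng)


@pytest.fixture
def params4(rng):
    return make_params(4, rng)


@pytest.fixture
def params20(rng):
    return make_params(20, rng)


def series_expm(q: np.ndarray, t: float) -> np.ndarray:
    """Scaling-and-squaring truncated-Taylor matrix exponential (test oracle)."""
    m = q * t
    norm = np.abs(m).sum(axis=1).max()
    squarings = max(0, int(np.ceil(np.log2(max(norm, 1e-300)))) + 4)
    a = m / (2**squarings)
    out = np.eye(q.shape[0])
    term = np.eye(q.shape[0])
    for k in range(1, 30):
        term = term @ a / k
        out = out + term
    for _ in range(squarings):
        out = out @ out
    return out
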