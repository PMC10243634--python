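import numpy as np
import pytest

from blockhmm import HMMModel


def random_model(rng: np.random.Generator, n_states: int) -> HMMModel:
    """A dense random model with comfortably non-degenerate parameters."""
    A = rng.random((n_states, n_states)) + 0.1
    A /= A.sum(axis=1, keepdims=True)
    init = rng.random(n_states) + 0.1
    init /= init.sum()
    return HMMModel(
        trans=A,
        means=rng.normal(0.0, 3.0, n_states),
        variances=rng.random(n_states) + 0.3,
        init=init,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230606)


@pytest.fixture
def two_state_model():
    """The worked two-state example: sticky chain, means 0 and 3."""
    return HMMModel(
        trans=[[0.9, 0.1], [0.1, 0.9]],
        means=[0.0, 3.0],
        variances=[1.0, 1.0],
        init=[0.5, 0.5],
    )


@pytest.fixture
def two_state_obs():
    return np.array([0.1, 2.9, 3.1])
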