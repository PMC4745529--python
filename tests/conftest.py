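import numpy as np
import pytest

from fsrasch import (
    SimulationConfig,
    fit_cml,
    score_households,
    simulate,
)


@pytest.fixture(scope="session")
def tororo_dataset():
    """One model-true dataset under the Tororo study conditions."""
    return simulate(SimulationConfig.from_preset("tororo", seed=42))


@pytest.fixture(scope="session")
def tororo_fit(tororo_dataset):
    return fit_cml(tororo_dataset.matrix)


@pytest.fixture(scope="session")
def tororo_scores(tororo_dataset, tororo_fit):
    return score_households(tororo_dataset.matrix, tororo_fit.params)


@pytest.fixture
def toy_two_item():
    """Two items; r = 1 households split 6:2 between patterns (1,0), (0,1).

    Closed form: beta_1 = (1/2) ln(6/2), SE = (1/2) sqrt(1/6 + 1/2).
    """
    return np.array([[1, 0]] * 6 + [[0, 1]] * 2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
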