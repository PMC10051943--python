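import numpy as np
import pytest

from affectdyn import OUModel, OUParams, simulate


@pytest.fixture(scope="session")
def ou_true_params():
    """A representative well-behaved parameter set used across tests."""
    return OUParams.from_natural(
        (0.4, -0.3), (2.0, 1.5), 0.3, (0.55, 0.45), 0.2, (0.01, 0.01)
    )


@pytest.fixture(scope="session")
def short_trajectory(ou_true_params):
    return simulate(ou_true_params, 1500, 0.04, seed=7)


@pytest.fixture(scope="session")
def fitted_ou(short_trajectory):
    return OUModel(short_trajectory).fit(draws=400, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
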