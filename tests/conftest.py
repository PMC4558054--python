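import numpy as np
import pytest

from choflux import (
    reference_experiments,
    reference_network,
    reference_parameters,
    simulate,
    toy_model,
)


@pytest.fixture(scope="session")
def ref_net():
    return reference_network()


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_exps():
    return reference_experiments()


@pytest.fixture(scope="session")
def ref_state(ref_exps):
    """Biogro-batch initial state as a plain dict."""
    return dict(ref_exps[0].initial_state)


@pytest.fixture(scope="session")
def biogro_batch_traj(ref_net, ref_params, ref_exps):
    return simulate(ref_net, ref_params, ref_exps[0])


@pytest.fixture(scope="session")
def toy():
    return toy_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
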