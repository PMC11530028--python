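import numpy as np
import pytest

import activityflow as af


@pytest.fixture(scope="session")
def config():
    return af.SimulationConfig(seed=7, n_participants=4)


@pytest.fixture(scope="session")
def model(config):
    return af.generate_ground_truth(config)


@pytest.fixture(scope="session")
def dataset(model, config):
    ds = af.simulate_task(model, config)
    ds.rest_timeseries = af.simulate_rest(model, config)
    return ds


def sem_sample(W, n_timepoints, noise_sd, rng):
    """Independent SEM sampler used as an oracle in several tests."""
    n = W.shape[0]
    e = rng.normal(0.0, noise_sd, size=(n, n_timepoints))
    return np.linalg.solve(np.eye(n) - W, e)
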