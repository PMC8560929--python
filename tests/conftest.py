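"""Shared fixtures: small networks and one cached scenario simulation.

The bundled scenario (24 regions, 2 EZ + 4 PZ) is simulated once per test
session; individual tests reuse the dataset, its features, and the
observation object instead of re-integrating the 5D network.
"""

import numpy as np
import pytest

from epimap.features import SEEGRecording, extract_log_power
from epimap.forward import (
    SeizureScenario,
    scenario_network,
    simulate_seizure_dataset,
)
from epimap.model import Observation, make_priors


@pytest.fixture(scope="session")
def bundled_network():
    connectome, gain = scenario_network(seed=0)
    return connectome, gain


@pytest.fixture(scope="session")
def bundled_dataset(bundled_network):
    connectome, gain = bundled_network
    dataset = simulate_seizure_dataset(SeizureScenario(), connectome, gain,
                                       seed=0)
    dataset.connectome = connectome
    return dataset


@pytest.fixture(scope="session")
def bundled_features(bundled_dataset):
    rec = SEEGRecording(samples=bundled_dataset.seeg_noisy,
                        sampling_rate=bundled_dataset.sampling_rate)
    return extract_log_power(rec, bundled_dataset.scenario.feature_config())


@pytest.fixture(scope="session")
def bundled_observation(bundled_dataset, bundled_features):
    return Observation(features=bundled_features, gain=bundled_dataset.gain)


@pytest.fixture(scope="session")
def small_problem():
    """4-region problem with synthetic-model-generated features, for
    gradient and posterior tests."""
    from epimap.forward import Connectome, GainMatrix
    from epimap.features import DataFeatures
    from epimap.model import predict_latent_states, unpack_theta

    rng = np.random.default_rng(7)
    n, T, m = 4, 60, 3
    C = rng.uniform(0.0, 1.0, (n, n))
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 0.0)
    connectome = Connectome(weights=C)
    priors = make_priors([0], n)
    theta_vec = priors.mean + 0.1 * rng.standard_normal(3 * n + 6)
    theta_vec[priors.truncated] = np.abs(theta_vec[priors.truncated])
    theta = unpack_theta(theta_vec, n)
    G = rng.uniform(0.1, 1.0, (m, n))
    latent = predict_latent_states(theta, connectome, T=T)
    S = np.log(G @ np.exp(latent.x)).T + 0.3 * rng.standard_normal((T, m))
    feats = DataFeatures(S=S, rho=np.mean(S ** 2, axis=0),
                         times=np.arange(T, dtype=float))
    obs = Observation(features=feats, gain=GainMatrix(G=G))
    return connectome, priors, obs, theta_vec
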