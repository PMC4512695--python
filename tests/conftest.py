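import numpy as np
import pytest

from noisygrowth import (
    LinearModelParams,
    LogisticModelParams,
    NoiseParams,
    stationary_beta_params,
)


@pytest.fixture
def ou_unit():
    """Unit noise: D = 1, tau_c = 1."""
    return NoiseParams(D=1.0, tau_c=1.0)


@pytest.fixture
def short_memory_noise():
    """Near-white regime at fixed D * tau_c = 1: tau_c = 0.01, D = 100."""
    return NoiseParams(D=100.0, tau_c=0.01)


@pytest.fixture
def linear_short_memory(short_memory_noise):
    return LinearModelParams(C0=1.0, noise=short_memory_noise)


@pytest.fixture
def logistic_short_memory(short_memory_noise):
    return LogisticModelParams(C0=1.0, gamma=1.0, epsilon=0.5, noise=short_memory_noise)


@pytest.fixture
def fig_like_logistic_sets():
    """Three canonical logistic parameterizations quoted by their stationary beta:
    (gamma, epsilon, beta*) = (1, 0.5, 500), (1, 0.5, 50), (0.5, 0.5, 5)."""
    tau_c = 0.01
    return [
        stationary_beta_params(500.0, 1.0, 0.5, tau_c),
        stationary_beta_params(50.0, 1.0, 0.5, tau_c),
        stationary_beta_params(5.0, 0.5, 0.5, tau_c),
    ]


@pytest.fixture
def uniform_grid():
    def make(t_end=10.0, dt=0.1):
        return np.arange(0.0, t_end + dt / 2, dt)

    return make
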