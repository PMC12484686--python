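import numpy as np
import pytest
from hypothesis import settings

import clockwave as cw

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def phase_params():
    """The reference phase-model parameter set used throughout the analysis."""
    return cw.PhaseModelParams()  # alpha=3, beta=1, k=10, omega=2pi, eps=0.1, D=3


@pytest.fixture(scope="session")
def sine_traj(phase_params):
    """A moderate-length noisy run under sinusoidal regulation."""
    f = cw.FourierRegFunction.sine(1)
    return cw.simulate_phase_output(phase_params, f, duration=2200.0, seed=314)


@pytest.fixture()
def rng():
    """Fresh, identically seeded generator per test: draws do not depend on
    which other tests ran before."""
    return np.random.default_rng(12345)
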