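import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240228)


@pytest.fixture(scope="session")
def analytic_pair():
    """A phase-locked analytic pair with a 90-degree lag, noise-free."""
    from neuroplex import OscillatorSpec, analytic_band, gen_oscillators

    lag = np.zeros((2, 2))
    lag[0, 1] = np.pi / 2
    coupling = np.array([[0.0, 1.0], [1.0, 0.0]])
    spec = OscillatorSpec(
        n_rois=2, coupling=coupling, phase_lag=lag, noise_sd=0.0, seed=7
    )
    ts = gen_oscillators(spec)
    return analytic_band(ts, (8.0, 12.0))
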