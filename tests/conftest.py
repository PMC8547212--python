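import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_sim_trace():
    """One 1 s simulated trace at bright, fast-diffusion conditions.

    20 particles, D = 50 um^2/s, mu0 = 100 kCps, r = 1, r0 = 0.4 um —
    the standard simulation conditions at a tenth of the duration.
    Shared across tests that only need a realistic diffusing trace.
    """
    from msmr import PSFGeometry, SimulationConfig, Species, simulate_trace
    cfg = SimulationConfig(
        species=(Species(D=50.0, count=20, mu0=100e3),),
        geometry=PSFGeometry(r0=0.4, z0=0.4),
        duration=1.0,
        seed=42,
    )
    return simulate_trace(cfg)
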