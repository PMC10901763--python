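import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pgrmap import SimulationParams, annotate_genomes, simulate

settings.register_profile(
    "pgrmap",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pgrmap")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_sim():
    """The reference simulation: 50 chromosomes, default parameters, seed 42."""
    params = SimulationParams(n_chromosomes=50, seed=42)
    mac, mic, truth = simulate(params)
    return params, mac, mic, truth


@pytest.fixture(scope="session")
def default_annotation(default_sim):
    """Full two-pass annotation of the reference simulation (computed once)."""
    _, mac, mic, _ = default_sim
    return annotate_genomes(mac, mic)
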