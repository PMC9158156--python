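import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220601)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    from famead import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_families=6, n_common_snps=2000, n_background_rare=12,
        n_prs_controls=100, replication_sizes=(60, 40, 300),
        n_unaffected_elderly=1, seed=11,
    )
    return simulate_cohort(cfg)
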