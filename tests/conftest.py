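import pytest

from mucpan.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(n_per_stratum=40, n_genes=400, n_probes=200, seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    """One small 4-stratum cohort shared across tests (read-only)."""
    return simulate_cohort(tiny_config, seed=3)
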