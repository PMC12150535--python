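import pytest

from diatraj.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but complete cohort configuration used across tests."""
    return SimulationConfig(
        n_per_subtype={"SIDD": 6, "SIRD": 6, "MOD": 6, "MARD": 12},
        n_controls=40,
        dropout_prob_per_exam=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)
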