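import pytest

from msomics.synthetic import (
    SimulationConfig,
    simulate_envelopes,
    simulate_metabolome,
    simulate_prm,
    simulate_tmt,
)


@pytest.fixture(scope="session")
def metabolome_sim():
    """Full-scale metabolome simulation (study conditions, seed 1)."""
    return simulate_metabolome(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_metabolome_sim():
    return simulate_metabolome(SimulationConfig(seed=2, n_compounds=20))


@pytest.fixture(scope="session")
def prm_sim():
    return simulate_prm(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def envelope_sim():
    return simulate_envelopes(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tmt_sim():
    return simulate_tmt(SimulationConfig(seed=1, n_proteins=300, n_effect_proteins=20))
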