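import pytest

from panelqc.simulate import (
    SimulationConfig,
    simulate_depth,
    simulate_reference_and_panel,
)


@pytest.fixture(scope="session")
def small_sim():
    """Deterministic desk-scale fixture: reference, panel and truth record."""
    config = SimulationConfig(seed=11)
    reference, panel, truth = simulate_reference_and_panel(config)
    return config, reference, panel, truth


@pytest.fixture(scope="session")
def small_profiles(small_sim):
    config, _reference, panel, truth = small_sim
    return simulate_depth(config, panel, truth)
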