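import pytest

from ecosel.simulate import FieldConfig, PanelConfig, simulate_field, simulate_panel


@pytest.fixture(scope="session")
def panel():
    """Default diversity panel: 123 genotypes x 3 blocks, 7 clusters."""
    traits, climate, truth = simulate_panel(PanelConfig(rng_seed=0))
    return traits, climate, truth


@pytest.fixture(scope="session")
def field():
    """Default field experiment: 294 treatment plots + 14 controls."""
    plots, truth = simulate_field(FieldConfig(rng_seed=0))
    return plots, truth
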