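import pytest

from srnakit.simulate import SimulationConfig, generate_reference, simulate_libraries


@pytest.fixture(scope="session")
def small_bundle():
    return generate_reference(12, 6, rng_seed=42)


@pytest.fixture(scope="session")
def small_sim(small_bundle):
    config = SimulationConfig(seed_edit_rate=0.01)
    return simulate_libraries(small_bundle, config, depth=10_000, rng_seed=43)
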