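import pytest

from germscreen import (
    EndpointMeasures,
    GerminationTimeCourse,
    SimulationConfig,
    generate_panel,
)


@pytest.fixture
def example_course():
    """11 seeds, cumulative counts 2,5,8,9,10,10,10: 10 of 11 germinated."""
    return GerminationTimeCourse(
        germplasm_id="A", condition="control", replicate=1,
        n_seeds=11, counts=(2, 5, 8, 9, 10, 10, 10),
    )


@pytest.fixture
def example_endpoint():
    return EndpointMeasures(
        germplasm_id="A", condition="control", replicate=1,
        root_length=5.0, fresh_weight=0.5, dry_weight=0.05,
    )


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel, shared across tests."""
    return generate_panel(SimulationConfig(n_germplasms=100, rng_seed=11))


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(SimulationConfig(n_germplasms=40, rng_seed=7))
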