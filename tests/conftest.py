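import pytest

from cascadesim import CapPolicy, ScenarioSpec, run_scenario
from cascadesim.synthetic import GeneratorConfig, generate_fixture, generate_landscape


@pytest.fixture
def tiny3():
    return generate_fixture("tiny3")


@pytest.fixture
def capbound():
    return generate_fixture("capbound")


@pytest.fixture
def singleprop():
    return generate_fixture("singleprop")


@pytest.fixture(scope="session")
def default_landscape():
    """Default synthetic landscape at a fixed seed, shared across tests."""
    return generate_landscape(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def truncate_runs(default_landscape):
    """100 constrained random-order replicates with the catchment cap
    enforced per-event (truncate mode)."""
    policy = CapPolicy(overshoot_mode="truncate", constrained=True)
    spec = ScenarioSpec(ordering="random", constrained=True, n_runs=100, seed=1)
    return run_scenario(default_landscape, policy, spec)
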