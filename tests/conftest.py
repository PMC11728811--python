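import pytest

import solventrisk as sr


@pytest.fixture(scope="session")
def scenario():
    """The packaged six-solvent default scenario."""
    return sr.default_scenario()


@pytest.fixture(scope="session")
def default_result(scenario):
    """One full 10,000-iteration run of the default scenario, shared across tests."""
    return sr.run_simulation(
        scenario.chemicals, scenario.model, scenario.groupings, n=10_000, seed=0
    )
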