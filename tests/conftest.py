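import pytest

import nof1sim as n1


@pytest.fixture(scope="session")
def graph():
    return n1.load_backpain_graph()


@pytest.fixture(scope="session")
def scen1_cohort(graph):
    """Small complete-data cohort without carry-over or interaction."""
    return n1.simulate_cohort(graph, n1.scenario_config(1), 8, seed=42)


@pytest.fixture(scope="session")
def scen2_cohort(graph):
    """Small complete-data cohort with carry-over."""
    return n1.simulate_cohort(graph, n1.scenario_config(2), 8, seed=42)
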