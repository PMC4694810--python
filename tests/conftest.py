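import networkx as nx
import pytest

from lfsn import RunConfig, ScenarioConfig, generate, run_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """Reference desk-scale scenario with planted synergistic pairs."""
    return generate(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """Full pipeline run on the reference scenario (test-scale random pool)."""
    return run_bundle(default_bundle, RunConfig(n_random=100, seed=1))


@pytest.fixture()
def path_graph_5():
    """a-b-c-d-e path."""
    g = nx.Graph()
    nx.add_path(g, list("abcde"))
    return g
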