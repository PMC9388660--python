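import networkx as nx
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # read-only fixtures shared across generated inputs
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def path_graph():
    """A -- B -- C -- D -- E."""
    g = nx.path_graph(5)
    return nx.relabel_nodes(g, dict(enumerate("ABCDE")))


@pytest.fixture
def complete_graph():
    g = nx.complete_graph(5)
    return nx.relabel_nodes(g, {i: f"K{i}" for i in g.nodes})
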