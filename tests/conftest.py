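import networkx as nx
import pytest

import heatpath as hp


def make_chain_graph() -> hp.LevelledGraph:
    """Minimal compound–reaction–pathway chain."""
    g = nx.Graph()
    g.add_node("c", level="compound")
    g.add_node("r", level="reaction")
    g.add_node("p", level="pathway")
    g.add_edge("c", "r")
    g.add_edge("r", "p")
    return hp.LevelledGraph(g, node_order=["c", "r", "p"])


@pytest.fixture
def chain_graph() -> hp.LevelledGraph:
    return make_chain_graph()


@pytest.fixture(scope="session")
def ora_toy() -> hp.LevelledGraph:
    """Ten compounds each in exactly one pathway; pathway A holds three."""
    return hp.bipartite_ora_graph((3, 3, 4))


@pytest.fixture(scope="session")
def ora_toy_input(ora_toy) -> hp.InputSet:
    """Four input compounds with two hits in pathway A (members: cpd_01..03)."""
    return hp.map_input(ora_toy, ["cpd_01", "cpd_02", "cpd_04", "cpd_07"])


@pytest.fixture(scope="session")
def small_graph() -> hp.LevelledGraph:
    """Connected 5-level synthetic graph of ~160 nodes."""
    return hp.generate_synthetic_graph(
        {"pathway": 5, "module": 4, "enzyme": 18, "reaction": 70, "compound": 60}, seed=11
    )


@pytest.fixture(scope="session")
def medium_graph() -> hp.LevelledGraph:
    """Benchmark-scale synthetic graph (~1000 nodes, KEGG sizes / 10)."""
    return hp.generate_synthetic_graph(hp.benchmark.BENCHMARK_SIZES, seed=5)
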