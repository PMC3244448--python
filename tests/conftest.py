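import networkx as nx
import pytest

from spanet.data_model import Annotation, AnnotationTable, interactome_from_edges


@pytest.fixture
def toy_spa():
    """Hand-traced expansion case.

    Core {A}; edges A-B, B-C, A-D, C-E.  Single-term aspects: B fully
    collection-annotated (admit); D carries an off-collection process term
    (reject); C has an unannotated process aspect (sentinel) plus
    collection function/component (admit); E carries an off-collection
    function term (reject).  Expected fixed point: nodes {A, B, C}, edges
    {A-B, B-C}.
    """
    g = interactome_from_edges([("A", "B"), ("B", "C"), ("A", "D"), ("C", "E")])
    table = AnnotationTable(
        {
            "A": Annotation.from_sets({"p1"}, {"f1"}, {"c1"}),
            "B": Annotation.from_sets({"p1"}, {"f1"}, {"c1"}),
            "C": Annotation.from_sets((), {"f1"}, {"c1"}),
            "D": Annotation.from_sets({"pX"}, {"f1"}, {"c1"}),
            "E": Annotation.from_sets({"p1"}, {"fX"}, {"c1"}),
        }
    )
    return g, table, ["A"]


@pytest.fixture
def path_graph5():
    return nx.path_graph([f"v{i}" for i in range(5)])


def nx_from_adj(adj):
    """Adjacency-dict (oracle form) -> networkx graph, isolates preserved."""
    g = nx.Graph()
    g.add_nodes_from(adj)
    for a, nbrs in adj.items():
        for b in nbrs:
            g.add_edge(a, b)
    return g
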