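import numpy as np
import pytest

from weavenet.graph_model import MixedGraph
from weavenet.ontology import AnnotationSet, OntologyDag, Term, propagate_annotations
from weavenet.synthetic_fixtures import FixtureSpec, make_mixed_graph


@pytest.fixture
def chain_dag():
    """root <- B <- A, plus a second branch root <- C."""
    dag = OntologyDag()
    for tid in ("GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"):
        dag.add_term(Term(tid, namespace="biological_process"))
    dag.add_parent("GO:0000002", "GO:0000001")  # B is_a root
    dag.add_parent("GO:0000003", "GO:0000002")  # A is_a B
    dag.add_parent("GO:0000004", "GO:0000001")  # C is_a root
    return dag


@pytest.fixture
def toy_graph():
    """Small hand-built mixed graph used across query/motif tests.

        s --- a --- x       (PPI chain)
        s --- b             (PPI)
        b --> x, tf --> s   (regulatory)
    """
    g = MixedGraph(species="toy")
    g.add_ppi_edge("s", "a")
    g.add_ppi_edge("a", "x")
    g.add_ppi_edge("s", "b")
    g.add_reg_edge("b", "x")
    g.add_reg_edge("tf", "s")
    return g


@pytest.fixture
def toy_annots(chain_dag):
    annots = AnnotationSet()
    annots.add("x", "GO:0000003")
    annots.add("b", "GO:0000003")
    return propagate_annotations(annots, chain_dag)


def random_mixed_graph(rng: np.random.Generator, n_nodes: int,
                       ppi_p: float = 0.25, reg_p: float = 0.12) -> MixedGraph:
    """Random small mixed graph for oracle comparisons."""
    g = MixedGraph()
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    for n in nodes:
        g.add_protein(n)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < ppi_p:
                g.add_ppi_edge(nodes[i], nodes[j])
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < reg_p:
                g.add_reg_edge(nodes[i], nodes[j])
    return g


@pytest.fixture(scope="session")
def small_fixture():
    """Session-scoped small planted-structure fixture for integration tests."""
    spec = FixtureSpec(protein_count=120, ppi_edge_p=0.06, reg_edge_count=120,
                       module_terms=4, members_per_term=12,
                       ontology_branching=5, seed=7)
    return make_mixed_graph(spec)
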