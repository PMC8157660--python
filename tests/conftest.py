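import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle importable

from adrmine.graph_core import Graph, canonicalize


def build_graph(
    property_edges=(),
    instantiation=(),
    subsumption=(),
    identity=(),
    labels=(),
) -> Graph:
    """Assemble a typed graph from plain tuples (test convenience)."""
    g = Graph()
    for s, p, o in property_edges:
        g.property_edges.add((s, p, o))
        g.entity_nodes.update((s, o))
    for s, c in instantiation:
        g.instantiation_edges.add((s, c))
        g.entity_nodes.add(s)
        g.class_nodes.add(c)
    for a, b in subsumption:
        g.subsumption_edges.add((a, b))
        g.class_nodes.update((a, b))
    for a, b in identity:
        g.identity_pairs.add(frozenset((a, b)))
        g.entity_nodes.update((a, b))
    for iri, value in labels:
        g.add_label(iri, value)
    return g


@pytest.fixture
def chain_cg():
    """d -p-> a -q-> b -r-> c, canonicalized (no identities)."""
    g = build_graph(property_edges=[("d", "p", "a"), ("a", "q", "b"), ("b", "r", "c")])
    return canonicalize(g)
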