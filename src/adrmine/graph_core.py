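"""Typed RDF graph model and owl:sameAs canonicalization.

A knowledge graph is read from N-Triples or Turtle into four typed edge
sets: property edges (ordinary predicates between entities), instantiation
edges (rdf:type), subsumption edges (rdfs:subClassOf) and identity pairs
(owl:sameAs).  Literal-object triples are discarded, except that
rdfs:label values are captured into a side table used for rendering.

Canonicalization contracts the connected components of the identity
relation into single nodes, pooling their edges: two nodes describing the
same drug in different sources then expose the union of their knowledge,
which is the prerequisite for mining drug neighborhoods.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import rdflib

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
RDFS_SUBCLASSOF = "http://www.w3.org/2000/01/rdf-schema#subClassOf"
RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
OWL_SAMEAS = "http://www.w3.org/2002/07/owl#sameAs"
OWL_CLASS = "http://www.w3.org/2002/07/owl#Class"
RDFS_CLASS = "http://www.w3.org/2000/01/rdf-schema#Class"
OWL_THING = "http://www.w3.org/2002/07/owl#Thing"

_CLASS_DECLARATIONS = frozenset({OWL_CLASS, RDFS_CLASS})

_DIALECT_FORMATS = {"ntriples": "nt", "turtle": "turtle"}


class InputError(Exception):
    """An input file is missing, unreadable, or malformed."""


@dataclass
class Graph:
    """A typed knowledge graph over IRI-identified nodes.

    ``labels`` maps an IRI to the sorted tuple of its rdfs:label values;
    the first entry is the primary display label.
    """

    entity_nodes: set[str] = field(default_factory=set)
    class_nodes: set[str] = field(default_factory=set)
    property_edges: set[tuple[str, str, str]] = field(default_factory=set)
    instantiation_edges: set[tuple[str, str]] = field(default_factory=set)
    subsumption_edges: set[tuple[str, str]] = field(default_factory=set)
    identity_pairs: set[frozenset[str]] = field(default_factory=set)
    labels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def nodes(self) -> set[str]:
        return self.entity_nodes | self.class_nodes

    def label(self, iri: str) -> str | None:
        """Primary display label for ``iri``, or None."""
        values = self.labels.get(iri)
        return values[0] if values else None

    def add_label(self, iri: str, value: str) -> None:
        current = set(self.labels.get(iri, ()))
        current.add(value)
        self.labels[iri] = tuple(sorted(current))

    def n_triples(self) -> int:
        return (
            len(self.property_edges)
            + len(self.instantiation_edges)
            + len(self.subsumption_edges)
            + len(self.identity_pairs)
        )


@dataclass
class CanonicalGraph:
    """An identity-contracted graph plus the node mapping that produced it."""

    graph: Graph
    representative_of: dict[str, str]

    def rep(self, iri: str) -> str:
        return self.representative_of.get(iri, iri)


def _term_id(term) -> str:
    if isinstance(term, rdflib.BNode):
        return "_:" + str(term)
    return str(term)


def read_rdf(sources: Iterable[str], dialect: str = "ntriples") -> Graph:
    """Parse RDF files into a typed :class:`Graph`.

    Triples are routed by predicate: rdf:type becomes an instantiation
    edge, rdfs:subClassOf a subsumption edge, owl:sameAs an identity pair,
    and everything else a property edge.  Triples whose object is a
    literal are dropped, except rdfs:label values which populate
    ``Graph.labels`` (they never become graph edges).
    """
    if dialect not in _DIALECT_FORMATS:
        raise InputError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_FORMATS)}")
    fmt = _DIALECT_FORMATS[dialect]
    g = Graph()
    for source in sources:
        rg = rdflib.Graph()
        try:
            if str(source).endswith(".gz"):
                with gzip.open(source, "rt", encoding="utf-8") as handle:
                    rg.parse(handle, format=fmt)
            else:
                rg.parse(source, format=fmt)
        except FileNotFoundError as exc:
            raise InputError(f"cannot read input file {source}") from exc
        except Exception as exc:  # rdflib BadSyntax carries line info in str()
            raise InputError(f"parse error in {source}: {exc}") from exc
        for s, p, o in rg:
            s_id, p_id = _term_id(s), _term_id(p)
            if isinstance(o, rdflib.Literal):
                if p_id == RDFS_LABEL:
                    g.add_label(s_id, str(o))
                continue
            o_id = _term_id(o)
            if p_id == RDF_TYPE:
                g.instantiation_edges.add((s_id, o_id))
                g.entity_nodes.add(s_id)
                g.class_nodes.add(o_id)
                if o_id in _CLASS_DECLARATIONS:
                    g.class_nodes.add(s_id)
            elif p_id == RDFS_SUBCLASSOF:
                g.subsumption_edges.add((s_id, o_id))
                g.class_nodes.add(s_id)
                g.class_nodes.add(o_id)
            elif p_id == OWL_SAMEAS:
                if s_id != o_id:
                    g.identity_pairs.add(frozenset((s_id, o_id)))
                g.entity_nodes.add(s_id)
                g.entity_nodes.add(o_id)
            else:
                g.property_edges.add((s_id, p_id, o_id))
                g.entity_nodes.add(s_id)
                g.entity_nodes.add(o_id)
    return g


def _identity_components(pairs: Iterable[frozenset[str]]) -> dict[str, str]:
    """Union-find over identity pairs; maps members to the lexicographically
    smallest IRI of their component."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for pair in pairs:
        members = sorted(pair)
        for m in members:
            parent.setdefault(m, m)
        if len(members) == 2:
            ra, rb = find(members[0]), find(members[1])
            if ra != rb:
                # keep the smaller IRI as root for determinism
                if rb < ra:
                    ra, rb = rb, ra
                parent[rb] = ra
    return {node: find(node) for node in parent}


def canonicalize(g: Graph, extra_identity_predicates: Iterable[str] = ()) -> CanonicalGraph:
    """Contract identity components into single canonical nodes.

    owl:sameAs is treated as symmetric and transitive; each connected
    component of the identity relation collapses onto its
    lexicographically smallest member.  Edge sets are rewritten through
    the mapping and deduplicated (set semantics); self-loops arising from
    contraction are kept.  Labels of merged nodes are pooled.

    ``extra_identity_predicates`` lets callers additionally contract
    predicates with identity-like semantics (e.g. skos:exactMatch): any
    property edge whose predicate is listed is consumed as an identity
    pair instead.  Off by default.
    """
    extra = set(extra_identity_predicates)
    pairs = set(g.identity_pairs)
    property_edges = g.property_edges
    if extra:
        property_edges = set()
        for s, p, o in g.property_edges:
            if p in extra:
                if s != o:
                    pairs.add(frozenset((s, o)))
            else:
                property_edges.add((s, p, o))

    rep = _identity_components(pairs)
    representative_of = {node: rep.get(node, node) for node in g.nodes()}
    r = lambda x: rep.get(x, x)

    out = Graph(
        entity_nodes={r(n) for n in g.entity_nodes},
        class_nodes={r(n) for n in g.class_nodes},
        property_edges={(r(s), p, r(o)) for s, p, o in property_edges},
        instantiation_edges={(r(s), r(c)) for s, c in g.instantiation_edges},
        subsumption_edges={(r(a), r(b)) for a, b in g.subsumption_edges},
    )
    for iri, values in g.labels.items():
        for value in values:
            out.add_label(r(iri), value)
    return CanonicalGraph(graph=out, representative_of=representative_of)


def _nt_term(iri: str) -> str:
    if iri.startswith("_:"):
        return iri
    return f"<{iri}>"


def _nt_literal(value: str) -> str:
    escaped = value.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")
    return f'"{escaped}"'


def write_ntriples(g: Graph, path: str) -> None:
    """Serialize a graph to N-Triples, one sorted line per triple.

    Sorting makes the output a deterministic function of the graph, so
    identical graphs serialize byte-identically.
    """
    lines = []
    for s, p, o in g.property_edges:
        lines.append(f"{_nt_term(s)} {_nt_term(p)} {_nt_term(o)} .")
    for s, c in g.instantiation_edges:
        lines.append(f"{_nt_term(s)} {_nt_term(RDF_TYPE)} {_nt_term(c)} .")
    for a, b in g.subsumption_edges:
        lines.append(f"{_nt_term(a)} {_nt_term(RDFS_SUBCLASSOF)} {_nt_term(b)} .")
    for pair in g.identity_pairs:
        a, b = sorted(pair)
        lines.append(f"{_nt_term(a)} {_nt_term(OWL_SAMEAS)} {_nt_term(b)} .")
    for iri in g.labels:
        for value in g.labels[iri]:
            lines.append(f"{_nt_term(iri)} {_nt_term(RDFS_LABEL)} {_nt_literal(value)} .")
    with open(path, "w", encoding="utf-8") as handle:
        for line in sorted(lines):
            handle.write(line + "\n")


def write_mapping_tsv(cg: CanonicalGraph, path: str) -> None:
    """Export representative_of as a two-column TSV (original, canonical)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("original_iri\tcanonical_iri\n")
        for original in sorted(cg.representative_of):
            handle.write(f"{original}\t{cg.representative_of[original]}\n")
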