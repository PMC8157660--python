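"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — recursive enumeration, repeated
set expansion, itertools products — and shares no traversal code with
the package, so agreement between the two is meaningful evidence.
"""

from __future__ import annotations

from itertools import product

import networkx as nx

from adrmine.graph_core import CanonicalGraph, Graph
from adrmine.mining import (
    CLASS,
    NODE,
    TOP_ELEMENT,
    MiningConfig,
    NeighborFeature,
    PathFeature,
)


def components_via_networkx(pairs):
    """Connected components of the identity relation, via networkx."""
    g = nx.Graph()
    for pair in pairs:
        members = sorted(pair)
        if len(members) == 1:
            g.add_node(members[0])
        else:
            g.add_edge(*members)
    return [set(c) for c in nx.connected_components(g)]


def _edges(cg: CanonicalGraph, cfg: MiningConfig):
    out = {}
    for s, p, o in cg.graph.property_edges:
        out.setdefault(s, set()).add((p, o))
        if cfg.undirected:
            out.setdefault(o, set()).add((p, s))
    return out


def _degree(cg: CanonicalGraph):
    deg = {}
    for s, p, o in cg.graph.property_edges:
        deg[s] = deg.get(s, 0) + 1
        deg[o] = deg.get(o, 0) + 1
    return deg


def _type_graph(cg: CanonicalGraph) -> nx.DiGraph:
    tg = nx.DiGraph()
    for s, c in cg.graph.instantiation_edges:
        tg.add_edge(("n", s), ("c", c))
    for a, b in cg.graph.subsumption_edges:
        tg.add_edge(("c", a), ("c", b))
    return tg


def type_closure_via_networkx(cg: CanonicalGraph, node: str) -> set[str]:
    tg = _type_graph(cg)
    if ("n", node) not in tg:
        return set()
    return {iri for kind, iri in nx.descendants(tg, ("n", node)) if kind == "c"}


def class_closure_via_networkx(cg: CanonicalGraph, cls: str) -> set[str]:
    tg = _type_graph(cg)
    closure = {cls}
    if ("c", cls) in tg:
        closure |= {iri for kind, iri in nx.descendants(tg, ("c", cls)) if kind == "c"}
    return closure


def _blocked(cg, node, cfg):
    return bool(cfg.b_exp_types) and bool(type_closure_via_networkx(cg, node) & cfg.b_exp_types)


def _admissible(cg, edges, node, cfg):
    for p, o in sorted(edges.get(node, ())):
        if p in cfg.b_predicates or _blocked(cg, o, cfg):
            continue
        yield p, o


def neighbors_oracle(cg: CanonicalGraph, root: str, cfg: MiningConfig) -> set[NeighborFeature]:
    """Level-by-level set expansion; hubs enter levels but are not expanded
    (the root always is)."""
    edges = _edges(cg, cfg)
    deg = _degree(cg)
    is_hub = lambda n: cfg.deg >= 0 and deg.get(n, 0) > cfg.deg
    reached = {root}
    level = {root}
    for _ in range(cfg.k):
        nxt = set()
        for n in level:
            if n != root and is_hub(n):
                continue
            for _, o in _admissible(cg, edges, n, cfg):
                if o not in reached:
                    nxt.add(o)
        reached |= nxt
        level = nxt
    reached.discard(root)
    return {NeighborFeature(n) for n in reached}


def walks_oracle(cg: CanonicalGraph, root: str, cfg: MiningConfig) -> set[tuple]:
    """All simple walks of length <= k from root, as (pred, node) tuples,
    by plain recursion (no support pruning)."""
    edges = _edges(cg, cfg)
    deg = _degree(cg)
    is_hub = lambda n: cfg.deg >= 0 and deg.get(n, 0) > cfg.deg
    walks: set[tuple] = set()

    def recurse(seq, last, visited):
        if len(seq) == cfg.k:
            return
        if seq and is_hub(last):  # root (empty seq) is always expanded
            return
        for p, o in _admissible(cg, edges, last, cfg):
            if o in visited:
                continue
            new = seq + ((p, o),)
            walks.add(new)
            recurse(new, o, visited | {o})

    recurse((), root, {root})
    return walks


def generalizer_oracle(cg: CanonicalGraph, node: str, cfg: MiningConfig) -> set[str]:
    """Classes within t steps of node by repeated single-step expansion
    over instantiation then subsumption edges."""
    direct_types = {}
    for s, c in cg.graph.instantiation_edges:
        direct_types.setdefault(s, set()).add(c)
    supers = {}
    for a, b in cg.graph.subsumption_edges:
        supers.setdefault(a, set()).add(b)
    limit = 10**9 if cfg.t == -1 else cfg.t
    if limit == 0:
        return set()
    frontier = set(direct_types.get(node, set()))
    reached = set(frontier)
    steps = 1
    while steps < limit and frontier:
        frontier = {sup for c in frontier for sup in supers.get(c, ())} - reached
        reached |= frontier
        steps += 1
    return {c for c in reached if c not in cfg.b_gen_types and c != cfg.top_iri}


def patterns_oracle(cg: CanonicalGraph, walk: tuple, cfg: MiningConfig) -> set[PathFeature]:
    options = []
    for _, node in walk:
        classes = sorted(generalizer_oracle(cg, node, cfg))
        options.append([(NODE, node)] + [(CLASS, c) for c in classes] + [TOP_ELEMENT])
    preds = [p for p, _ in walk]
    out = set()
    for combo in product(*options):
        if all(el[0] == NODE for el in combo):
            continue
        out.add(PathFeature(tuple(zip(preds, combo))))
    return out


def element_leq_oracle(cg, e1, e2) -> bool:
    if e1 == e2:
        return True
    if e2 == TOP_ELEMENT:
        return True
    if e1 == TOP_ELEMENT:
        return False
    k1, i1 = e1
    k2, i2 = e2
    if k2 == CLASS:
        if k1 == NODE:
            return i2 in type_closure_via_networkx(cg, i1)
        return i2 in class_closure_via_networkx(cg, i1)
    return False


def more_specific_oracle(cg, f1, f2) -> bool:
    if isinstance(f1, NeighborFeature) or isinstance(f2, NeighborFeature):
        return f1 == f2
    if len(f1.steps) != len(f2.steps):
        return False
    if tuple(p for p, _ in f1.steps) != tuple(p for p, _ in f2.steps):
        return False
    return all(
        element_leq_oracle(cg, e1, e2)
        for (_, e1), (_, e2) in zip(f1.steps, f2.steps)
    )


def _matches_category(cg, element, prefixes, classes):
    kind, iri = element
    if kind == "top":
        return False
    if any(iri.startswith(p) for p in prefixes) or iri in classes:
        return True
    if kind == NODE and classes:
        return bool(type_closure_via_networkx(cg, iri) & set(classes))
    return False


def mine_oracle(cg: CanonicalGraph, drugs, cfg: MiningConfig, vocab=None) -> dict:
    """Composition of the naive pieces: exhaustive enumeration, then the
    support, specificity, and domain filters.  Returns feature -> support."""
    drugs = sorted(set(drugs))
    nodes = cg.graph.nodes()
    support: dict = {}
    for root in drugs:
        if root not in nodes:
            continue
        for feat in neighbors_oracle(cg, root, cfg):
            support.setdefault(feat, set()).add(root)
        for walk in walks_oracle(cg, root, cfg):
            feat = PathFeature(tuple((p, (NODE, o)) for p, o in walk))
            support.setdefault(feat, set()).add(root)

    # paths below s_min are dropped before pattern generation
    paths = {
        f: s
        for f, s in support.items()
        if isinstance(f, PathFeature) and len(s) >= cfg.s_min
    }
    support = {
        f: s
        for f, s in support.items()
        if isinstance(f, NeighborFeature) or f in paths
    }
    for path, s in paths.items():
        walk = tuple((p, el[1]) for p, el in path.steps)
        for pattern in patterns_oracle(cg, walk, cfg):
            support.setdefault(pattern, set()).update(s)

    s_max = float("inf") if cfg.s_max is None else cfg.s_max
    support = {f: s for f, s in support.items() if cfg.s_min <= len(s) <= s_max}

    kept = {}
    features = list(support)
    for f in features:
        removed = any(
            other != f
            and frozenset(support[other]) == frozenset(support[f])
            and more_specific_oracle(cg, other, f)
            for other in features
        )
        if not removed:
            kept[f] = support[f]
    support = kept

    if cfg.m != "no-check":
        cat_names = {"p": "pathway", "g": "gene_or_go", "m": "mesh"}
        cats = [vocab.category(cat_names[letter]) for letter in cfg.m]
        filtered = {}
        for f, s in support.items():
            if isinstance(f, NeighborFeature):
                elements = [(NODE, f.node)]
            else:
                elements = [el for _, el in f.steps]
            if any(
                _matches_category(cg, el, prefixes, classes)
                for el in elements
                for prefixes, classes in cats
            ):
                filtered[f] = s
        support = filtered
    return {f: frozenset(s) for f, s in support.items()}


def random_graph(rng, max_triples: int = 200) -> Graph:
    """A small random typed graph with hierarchy, identity pairs, and
    enough structural variety to exercise every filter."""
    g = Graph()
    n_classes = int(rng.integers(3, 7))
    classes = [f"http://r.org/cls/C{i}" for i in range(n_classes)]
    g.class_nodes.update(classes)
    for i in range(1, n_classes):
        parent = classes[int(rng.integers(0, i))]
        g.subsumption_edges.add((classes[i], parent))
    n_nodes = int(rng.integers(6, 16))
    namespaces = ["http://r.org/a/", "http://r.org/b/", "http://r.org/c/"]
    nodes = [
        namespaces[int(rng.integers(0, 3))] + f"n{i}" for i in range(n_nodes)
    ]
    g.entity_nodes.update(nodes)
    for node in nodes:
        for _ in range(int(rng.integers(0, 3))):
            g.instantiation_edges.add((node, classes[int(rng.integers(0, n_classes))]))
    predicates = [f"http://r.org/p/p{i}" for i in range(int(rng.integers(2, 5)))]
    n_edges = int(rng.integers(n_nodes, min(max_triples - g.n_triples(), 4 * n_nodes)))
    for _ in range(max(0, n_edges)):
        s = nodes[int(rng.integers(0, n_nodes))]
        o = nodes[int(rng.integers(0, n_nodes))]
        g.property_edges.add((s, predicates[int(rng.integers(0, len(predicates)))], o))
    for _ in range(int(rng.integers(0, 3))):
        a = nodes[int(rng.integers(0, n_nodes))]
        b = nodes[int(rng.integers(0, n_nodes))]
        if a != b:
            g.identity_pairs.add(frozenset((a, b)))
    return g


def random_vocab(rng, graph: Graph):
    """A random non-empty vocabulary over the graph's namespaces/classes."""
    from adrmine.mining import DomainVocabulary

    classes = sorted(graph.class_nodes)
    pick_cls = lambda: frozenset(
        {classes[int(rng.integers(0, len(classes)))]} if classes else set()
    )
    prefixes = ("http://r.org/a/", "http://r.org/b/", "http://r.org/c/")
    pick_pref = lambda: (prefixes[int(rng.integers(0, len(prefixes)))],)
    return DomainVocabulary(
        pathway_prefixes=pick_pref(),
        pathway_classes=pick_cls(),
        gene_or_go_prefixes=pick_pref(),
        gene_or_go_classes=pick_cls(),
        mesh_prefixes=pick_pref(),
        mesh_classes=pick_cls(),
    )


def random_config(rng, graph: Graph) -> MiningConfig:
    predicates = sorted({p for _, p, _ in graph.property_edges})
    classes = sorted(graph.class_nodes)
    b_predicates = set()
    if predicates and rng.random() < 0.4:
        b_predicates.add(predicates[int(rng.integers(0, len(predicates)))])
    b_exp = set()
    if classes and rng.random() < 0.4:
        b_exp.add(classes[int(rng.integers(0, len(classes)))])
    b_gen = set()
    if classes and rng.random() < 0.4:
        b_gen.add(classes[int(rng.integers(0, len(classes)))])
    return MiningConfig(
        k=int(rng.integers(1, 4)),
        t=int(rng.choice([-1, 0, 1, 2, 3])),
        deg=int(rng.choice([-1, 3, 5, 1000])),
        s_min=int(rng.integers(0, 3)),
        s_max=None if rng.random() < 0.7 else int(rng.integers(3, 8)),
        undirected=bool(rng.random() < 0.4),
        b_predicates=frozenset(b_predicates),
        b_exp_types=frozenset(b_exp),
        b_gen_types=frozenset(b_gen),
        m="no-check" if rng.random() < 0.5 else str(rng.choice(["p", "g", "m", "pg", "pgm"])),
        top_iri="http://r.org/cls/Top",
    )
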