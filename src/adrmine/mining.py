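"""Neighbor, path, and path-pattern feature mining over a canonical graph.

Drugs are described by three kinds of binary features mined from their
graph neighborhood:

* **neighbors** — any node reachable within ``k`` hops (distance is not
  recorded: the same node reached at depths 2 and 3 is one feature);
* **paths** — sequences ``-p1-> n1 -p2-> n2 ...`` of length at most ``k``
  rooted at a drug;
* **path patterns** — paths with one or more node positions generalized
  to an ontology class the node (transitively) instantiates, or to the
  top class ⊤.  A node is only generalized by classes at most ``t``
  instantiation/subsumption steps away; ⊤ is always admissible.

Topological filters keep the feature space tractable: a predicate
blacklist, a blacklist of entity types never traversed, a hub cutoff
``deg`` (hubs are reachable but never expanded), and inclusive support
bounds ``[s_min, s_max]``.  Among features carried by exactly the same
drugs, only the most specific are kept (antichain per support group).
A final domain filter ``m`` keeps only features mentioning a pathway,
gene/GO, or MeSH element, in any disjunctive combination.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping

from .graph_core import CanonicalGraph, OWL_THING, RDF_TYPE

NODE = "node"
CLASS = "class"
TOP = "top"

#: element of a path step: (NODE, iri) | (CLASS, iri) | (TOP, None)
Element = tuple[str, str | None]
TOP_ELEMENT: Element = (TOP, None)

VALID_M = ("no-check", "p", "g", "m", "pg", "pgm")

_M_CATEGORY = {"p": "pathway", "g": "gene_or_go", "m": "mesh"}


class ConfigurationError(Exception):
    """A mining parameter or vocabulary is invalid."""


@dataclass(frozen=True)
class MiningConfig:
    """Parameter bundle limiting the number of mined features.

    Parameters
    ----------
    k : maximum path length (and neighbor distance), k >= 1.
    t : maximum generalization depth; -1 means unlimited; instantiation
        counts as one step, each subsumption hop as one more.
    deg : hub cutoff — nodes with more than ``deg`` incident property
        edges are never expanded; -1 disables the cutoff.
    s_min, s_max : inclusive support bounds; s_max=None means +inf.
    undirected : traverse property edges in both directions (keeping the
        predicate label) instead of outgoing only.
    b_predicates : predicates never traversed (rdf:type by default, so
        exploration goes through entities, not classes).
    b_exp_types : classes whose direct or indirect instances are never
        entered during traversal.
    b_gen_types : classes never used as generalizers (still traversed
        when counting generalization distance).
    m : domain filter, one of {no-check, p, g, m, pg, pgm}.
    top_iri : IRI rendered for the top class ⊤.
    """

    k: int = 3
    t: int = 3
    deg: int = 500
    s_min: int = 5
    s_max: int | None = None
    undirected: bool = False
    b_predicates: frozenset[str] = frozenset({RDF_TYPE})
    b_exp_types: frozenset[str] = frozenset()
    b_gen_types: frozenset[str] = frozenset()
    m: str = "pgm"
    top_iri: str = OWL_THING

    def __post_init__(self):
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.t < -1:
            raise ConfigurationError(f"t must be >= -1, got {self.t}")
        if self.deg < -1:
            raise ConfigurationError(f"deg must be >= -1, got {self.deg}")
        if self.s_min < 0:
            raise ConfigurationError(f"s_min must be >= 0, got {self.s_min}")
        if self.s_max is not None and self.s_min > self.s_max:
            raise ConfigurationError(f"s_min={self.s_min} exceeds s_max={self.s_max}")
        if self.m not in VALID_M:
            raise ConfigurationError(f"m must be one of {VALID_M}, got {self.m!r}")
        object.__setattr__(self, "b_predicates", frozenset(self.b_predicates))
        object.__setattr__(self, "b_exp_types", frozenset(self.b_exp_types))
        object.__setattr__(self, "b_gen_types", frozenset(self.b_gen_types))

    @property
    def s_max_value(self) -> float:
        return math.inf if self.s_max is None else self.s_max


@dataclass(frozen=True)
class PathFeature:
    """A predicate-element sequence rooted at a drug.

    ``steps`` is a tuple of (predicate IRI, element); an element is a
    concrete node, an ontology class, or ⊤.  The feature is a *pattern*
    iff at least one element is a class or ⊤.
    """

    steps: tuple[tuple[str, Element], ...]

    @property
    def is_pattern(self) -> bool:
        return any(el[0] != NODE for _, el in self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def predicates(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.steps)


@dataclass(frozen=True)
class NeighborFeature:
    """A node reachable from a drug within k hops (distance-free)."""

    node: str


Feature = PathFeature | NeighborFeature


@dataclass
class FeatureRecord:
    feature: Feature
    support: frozenset[str]


@dataclass(frozen=True)
class DomainVocabulary:
    """Per-category IRI namespaces and class sets for the domain filter.

    Categories (pathway / gene_or_go / mesh) are checked independently;
    an element matches a category if its IRI starts with a listed prefix,
    is a listed class, or — for entity nodes — some class it transitively
    instantiates is listed (an entity "is a pathway" through its type).
    """

    pathway_prefixes: tuple[str, ...] = ()
    pathway_classes: frozenset[str] = frozenset()
    gene_or_go_prefixes: tuple[str, ...] = ()
    gene_or_go_classes: frozenset[str] = frozenset()
    mesh_prefixes: tuple[str, ...] = ()
    mesh_classes: frozenset[str] = frozenset()

    def category(self, name: str) -> tuple[tuple[str, ...], frozenset[str]]:
        return (
            getattr(self, f"{name}_prefixes"),
            getattr(self, f"{name}_classes"),
        )

    def is_empty(self, name: str) -> bool:
        prefixes, classes = self.category(name)
        return not prefixes and not classes


# ---------------------------------------------------------------------------
# Graph index: adjacency, degrees, and closure caches over a canonical graph.


class GraphIndex:
    """Traversal-oriented view of a canonical graph with memoized closures."""

    def __init__(self, cg: CanonicalGraph):
        g = cg.graph
        out: dict[str, list[tuple[str, str]]] = {}
        inc: dict[str, list[tuple[str, str]]] = {}
        for s, p, o in g.property_edges:
            out.setdefault(s, []).append((p, o))
            inc.setdefault(o, []).append((p, s))
        self.out = {n: tuple(sorted(v)) for n, v in out.items()}
        self.inc = {n: tuple(sorted(v)) for n, v in inc.items()}
        self.degree = {
            n: len(self.out.get(n, ())) + len(self.inc.get(n, ()))
            for n in set(self.out) | set(self.inc)
        }
        types: dict[str, set[str]] = {}
        for s, c in g.instantiation_edges:
            types.setdefault(s, set()).add(c)
        self.direct_types = types
        supers: dict[str, set[str]] = {}
        for a, b in g.subsumption_edges:
            supers.setdefault(a, set()).add(b)
        self.direct_supers = supers
        self.nodes = g.nodes()
        self._type_closure: dict[str, frozenset[str]] = {}
        self._class_closure: dict[str, frozenset[str]] = {}
        self._generalizers: dict[tuple, tuple[str, ...]] = {}

    def class_closure(self, c: str) -> frozenset[str]:
        """{c} plus all transitive superclasses."""
        cached = self._class_closure.get(c)
        if cached is not None:
            return cached
        seen = {c}
        stack = [c]
        while stack:
            for sup in self.direct_supers.get(stack.pop(), ()):
                if sup not in seen:
                    seen.add(sup)
                    stack.append(sup)
        result = frozenset(seen)
        self._class_closure[c] = result
        return result

    def type_closure(self, n: str) -> frozenset[str]:
        """All classes n instantiates, directly or through subclass edges."""
        cached = self._type_closure.get(n)
        if cached is not None:
            return cached
        closure: set[str] = set()
        for c in self.direct_types.get(n, ()):
            closure |= self.class_closure(c)
        result = frozenset(closure)
        self._type_closure[n] = result
        return result

    def generalizers(self, n: str, t: int, b_gen: frozenset[str], top_iri: str) -> tuple[str, ...]:
        """Classes within distance t of n (instantiation = 1 step, each
        subsumption hop = 1 more), blacklisted classes removed from the
        result but still traversed; the top IRI is folded into ⊤."""
        key = (n, t, b_gen, top_iri)
        cached = self._generalizers.get(key)
        if cached is not None:
            return cached
        if t == 0:
            result: tuple[str, ...] = ()
            self._generalizers[key] = result
            return result
        limit = math.inf if t == -1 else t
        dist: dict[str, int] = {}
        queue: deque[tuple[str, int]] = deque()
        for c in self.direct_types.get(n, ()):
            if c not in dist:
                dist[c] = 1
                queue.append((c, 1))
        while queue:
            c, d = queue.popleft()
            if d >= limit:
                continue
            for sup in self.direct_supers.get(c, ()):
                if sup not in dist:
                    dist[sup] = d + 1
                    queue.append((sup, d + 1))
        result = tuple(sorted(c for c in dist if c not in b_gen and c != top_iri))
        self._generalizers[key] = result
        return result

    def is_hub(self, n: str, deg: int) -> bool:
        return deg >= 0 and self.degree.get(n, 0) > deg

    def blocked(self, n: str, b_exp_types: frozenset[str]) -> bool:
        return bool(b_exp_types) and bool(self.type_closure(n) & b_exp_types)

    def successors(self, n: str, cfg: MiningConfig) -> list[tuple[str, str]]:
        """Admissible traversal steps out of n (ignoring the hub cutoff,
        which the caller applies to n itself before expanding)."""
        steps = []
        for p, o in self.out.get(n, ()):
            if p in cfg.b_predicates or self.blocked(o, cfg.b_exp_types):
                continue
            steps.append((p, o))
        if cfg.undirected:
            for p, s in self.inc.get(n, ()):
                if p in cfg.b_predicates or self.blocked(s, cfg.b_exp_types):
                    continue
                steps.append((p, s))
        return steps


def index_of(cg: CanonicalGraph) -> GraphIndex:
    idx = getattr(cg, "_adrmine_index", None)
    if idx is None:
        idx = GraphIndex(cg)
        cg._adrmine_index = idx
    return idx


# ---------------------------------------------------------------------------
# Neighbor and path enumeration.


def reachable_neighbors(
    cg: CanonicalGraph, roots: Iterable[str], cfg: MiningConfig
) -> dict[str, set[NeighborFeature]]:
    """Breadth-limited neighborhoods: all nodes within k hops of each root.

    Hub nodes are recorded as neighbors but never expanded; blacklisted
    predicates and blacklisted-type nodes are never traversed; a root is
    excluded from its own neighbor set.  Roots themselves are always
    expanded regardless of their degree.
    """
    idx = index_of(cg)
    result: dict[str, set[NeighborFeature]] = {}
    for root in sorted(set(roots)):
        if root not in idx.nodes:
            warnings.warn(f"root {root} absent from graph; empty neighbor set")
            result[root] = set()
            continue
        visited = {root}
        frontier = [root]
        depth = 0
        while frontier and depth < cfg.k:
            depth += 1
            nxt = []
            for n in frontier:
                if n != root and idx.is_hub(n, cfg.deg):
                    continue  # reachable but never expanded
                for _, o in idx.successors(n, cfg):
                    if o not in visited:
                        visited.add(o)
                        nxt.append(o)
            frontier = nxt
        visited.discard(root)
        result[root] = {NeighborFeature(n) for n in visited}
    return result


def enumerate_paths(
    cg: CanonicalGraph, roots: Iterable[str], cfg: MiningConfig
) -> dict[PathFeature, frozenset[str]]:
    """All simple walks of length <= k from the roots, as path features.

    A feature's support is the set of roots from which its step sequence
    is realizable.  Sequences whose support falls below ``s_min`` are
    pruned (support is anti-monotone along prefixes, so pruning a prefix
    cannot lose any admissible longer path), and the returned paths all
    satisfy the lower support bound.
    """
    idx = index_of(cg)
    roots = sorted(set(r for r in roots if r in idx.nodes))
    # realizations: sequence of (pred, node) steps -> list of (root, last, visited)
    frontier: dict[tuple, list[tuple[str, str, frozenset[str]]]] = {}
    for root in roots:
        for p, o in idx.successors(root, cfg):
            if o == root:
                continue
            seq = ((p, o),)
            frontier.setdefault(seq, []).append((root, o, frozenset((root, o))))
    all_supports: dict[tuple, set[str]] = {}
    for depth in range(1, cfg.k + 1):
        nxt: dict[tuple, list[tuple[str, str, frozenset[str]]]] = {}
        for seq, realizations in frontier.items():
            support = {r for r, _, _ in realizations}
            if len(support) < cfg.s_min:
                continue
            all_supports[seq] = support
            if depth == cfg.k:
                continue
            for root, last, visited in realizations:
                if idx.is_hub(last, cfg.deg):
                    continue
                for p, o in idx.successors(last, cfg):
                    if o in visited:
                        continue
                    new_seq = seq + ((p, o),)
                    nxt.setdefault(new_seq, []).append((root, o, visited | {o}))
        frontier = nxt
    return {
        PathFeature(tuple((p, (NODE, o)) for p, o in seq)): frozenset(support)
        for seq, support in all_supports.items()
    }


# ---------------------------------------------------------------------------
# Generalization into path patterns.


def _position_options(idx: GraphIndex, element: Element, cfg: MiningConfig) -> list[Element]:
    assert element[0] == NODE
    classes = idx.generalizers(element[1], cfg.t, cfg.b_gen_types, cfg.top_iri)
    return [element] + [(CLASS, c) for c in classes] + [TOP_ELEMENT]


def generalize_path(path: PathFeature, cg: CanonicalGraph, cfg: MiningConfig) -> set[PathFeature]:
    """All patterns generalizing a concrete path.

    Each position may keep its node, be replaced by a class at most ``t``
    instantiation/subsumption steps away (blacklisted generalizer classes
    excluded), or by ⊤ (always admissible).  The all-original combination
    is excluded, so a path with ``c_i`` admissible classes at position
    ``i`` yields ``prod(c_i + 2) - 1`` patterns.
    """
    if path.is_pattern:
        raise ValueError("can only generalize a concrete path, not a pattern")
    idx = index_of(cg)
    options = [_position_options(idx, el, cfg) for _, el in path.steps]
    predicates = path.predicates
    patterns: set[PathFeature] = set()
    for combo in product(*options):
        steps = tuple(zip(predicates, combo))
        if all(el[0] == NODE for el in combo):
            continue
        patterns.add(PathFeature(steps))
    return patterns


# ---------------------------------------------------------------------------
# Specificity ordering and filters.


def _element_leq(idx: GraphIndex, e1: Element, e2: Element) -> bool:
    """True iff e1 is at least as specific as e2."""
    if e1 == e2:
        return True
    kind2 = e2[0]
    if kind2 == TOP:
        return True
    kind1 = e1[0]
    if kind1 == TOP:
        return False
    if kind2 == CLASS:
        if kind1 == NODE:
            return e2[1] in idx.type_closure(e1[1])
        return e2[1] in idx.class_closure(e1[1])
    return False  # e2 is a node and e1 != e2


def is_more_specific(f1: Feature, f2: Feature, cg: CanonicalGraph) -> bool:
    """True iff f1 is at least as specific as f2 (reflexive).

    Paths/patterns compare positionwise when lengths and predicate
    sequences align: a node is more specific than any class it
    transitively instantiates, a class than any of its superclasses, and
    everything than ⊤.  Neighbor features compare only by equality.
    """
    if isinstance(f1, NeighborFeature) or isinstance(f2, NeighborFeature):
        return f1 == f2
    if len(f1) != len(f2) or f1.predicates != f2.predicates:
        return False
    idx = index_of(cg)
    return all(
        _element_leq(idx, e1, e2)
        for (_, e1), (_, e2) in zip(f1.steps, f2.steps)
    )


def specificity_filter(
    records: Iterable[FeatureRecord], cg: CanonicalGraph
) -> list[FeatureRecord]:
    """Keep only the most specific features within each identical-support
    group: a record strictly generalized by another with the exact same
    support set is removed, leaving an antichain per group."""
    idx = index_of(cg)
    groups: dict[tuple, list[FeatureRecord]] = {}
    passthrough: list[FeatureRecord] = []
    for rec in records:
        if isinstance(rec.feature, NeighborFeature):
            passthrough.append(rec)  # neighbors are incomparable to paths
            continue
        key = (rec.support, rec.feature.predicates)
        groups.setdefault(key, []).append(rec)
    kept: list[FeatureRecord] = list(passthrough)
    for group in groups.values():
        if len(group) == 1:
            kept.extend(group)
            continue
        for rec in group:
            generalized = any(
                other.feature != rec.feature
                and is_more_specific(other.feature, rec.feature, cg)
                for other in group
            )
            if not generalized:
                kept.append(rec)
    return kept


def support_filter(
    records: Iterable[FeatureRecord], s_min: int, s_max: int | None
) -> list[FeatureRecord]:
    """Keep records whose support size lies in the inclusive [s_min, s_max]."""
    hi = math.inf if s_max is None else s_max
    return [r for r in records if s_min <= len(r.support) <= hi]


def _feature_elements(feature: Feature) -> list[Element]:
    if isinstance(feature, NeighborFeature):
        return [(NODE, feature.node)]
    return [el for _, el in feature.steps]


def _element_matches(idx: GraphIndex, element: Element, prefixes, classes) -> bool:
    kind, iri = element
    if kind == TOP:
        return False
    if any(iri.startswith(pref) for pref in prefixes) or iri in classes:
        return True
    if kind == NODE and classes:
        return bool(idx.type_closure(iri) & classes)
    return False


def domain_filter(
    records: Iterable[FeatureRecord],
    m: str,
    vocab: DomainVocabulary | None,
    cg: CanonicalGraph,
) -> list[FeatureRecord]:
    """Keep features mentioning at least one element of a category named
    by m's letters (disjunction); m='no-check' passes everything."""
    records = list(records)
    if m == "no-check":
        return records
    if m not in VALID_M:
        raise ConfigurationError(f"m must be one of {VALID_M}, got {m!r}")
    if vocab is None:
        raise ConfigurationError(f"domain filter m={m!r} requires a vocabulary")
    categories = []
    for letter in m:
        name = _M_CATEGORY[letter]
        if vocab.is_empty(name):
            raise ConfigurationError(f"domain filter m={m!r} needs a non-empty {name} vocabulary")
        categories.append(vocab.category(name))
    idx = index_of(cg)
    kept = []
    for rec in records:
        elements = _feature_elements(rec.feature)
        if any(
            _element_matches(idx, el, prefixes, classes)
            for el in elements
            for prefixes, classes in categories
        ):
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Feature table and orchestration.


def serialize_element(element: Element, top_iri: str) -> str:
    kind, iri = element
    if kind == TOP:
        return f"TOP({top_iri})"
    if kind == CLASS:
        return f"CLASS({iri})"
    return iri


def serialize_feature(feature: Feature, top_iri: str = OWL_THING) -> str:
    if isinstance(feature, NeighborFeature):
        return f"NEIGHBOR|{feature.node}"
    parts = [f"{p}->{serialize_element(el, top_iri)}" for p, el in feature.steps]
    kind = "PATTERN" if feature.is_pattern else "PATH"
    return f"{kind}|" + "|".join(parts)


@dataclass
class FeatureTable:
    """Mined features with their drug-support sets."""

    records: list[FeatureRecord] = field(default_factory=list)
    top_iri: str = OWL_THING

    def __len__(self) -> int:
        return len(self.records)

    def feature_ids(self) -> list[str]:
        return sorted(serialize_feature(r.feature, self.top_iri) for r in self.records)

    def by_id(self) -> dict[str, FeatureRecord]:
        return {serialize_feature(r.feature, self.top_iri): r for r in self.records}

    def supports(self) -> dict[str, frozenset[str]]:
        return {fid: rec.support for fid, rec in self.by_id().items()}

    def kind_of(self, rec: FeatureRecord) -> str:
        if isinstance(rec.feature, NeighborFeature):
            return "neighbor"
        return "pattern" if rec.feature.is_pattern else "path"

    def write_tsv(self, coords_path: str, meta_path: str) -> None:
        """Export as sparse coordinates (drug, feature_id) plus metadata."""
        by_id = self.by_id()
        with open(coords_path, "w", encoding="utf-8") as handle:
            handle.write("drug_iri\tfeature_id\n")
            for fid in sorted(by_id):
                for drug in sorted(by_id[fid].support):
                    handle.write(f"{drug}\t{fid}\n")
        with open(meta_path, "w", encoding="utf-8") as handle:
            handle.write("feature_id\tkind\tsupport_size\n")
            for fid in sorted(by_id):
                rec = by_id[fid]
                handle.write(f"{fid}\t{self.kind_of(rec)}\t{len(rec.support)}\n")


def mine_features(
    cg: CanonicalGraph,
    drugs: Iterable[str],
    cfg: MiningConfig,
    vocab: DomainVocabulary | None = None,
) -> FeatureTable:
    """Full mining pipeline for a set of labeled drugs.

    Order: enumerate neighbors and paths (with lower-support pruning of
    paths), generalize surviving paths into patterns (a pattern's support
    is the union of the supports of the paths it generalizes), then apply
    the support, specificity, and domain filters.
    """
    drugs = sorted(set(drugs))
    if not drugs:
        return FeatureTable(records=[], top_iri=cfg.top_iri)

    neighbor_map = reachable_neighbors(cg, drugs, cfg)
    neighbor_support: dict[NeighborFeature, set[str]] = {}
    for root, feats in neighbor_map.items():
        for feat in feats:
            neighbor_support.setdefault(feat, set()).add(root)

    path_support = enumerate_paths(cg, drugs, cfg)

    pattern_support: dict[PathFeature, set[str]] = {}
    for path, support in path_support.items():
        for pattern in generalize_path(path, cg, cfg):
            pattern_support.setdefault(pattern, set()).update(support)

    records = (
        [FeatureRecord(f, frozenset(s)) for f, s in neighbor_support.items()]
        + [FeatureRecord(f, s) for f, s in path_support.items()]
        + [FeatureRecord(f, frozenset(s)) for f, s in pattern_support.items()]
    )
    records = support_filter(records, cfg.s_min, cfg.s_max)
    records = specificity_filter(records, cg)
    records = domain_filter(records, cfg.m, vocab, cg)
    key = lambda r: serialize_feature(r.feature, cfg.top_iri)
    return FeatureTable(records=sorted(records, key=key), top_iri=cfg.top_iri)
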