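"""Feature mining: traversal, generalization, specificity, filters.

The deepest check is oracle equivalence: the full pipeline must agree
with an independent brute-force enumerator on random graphs across the
parameter grid.
"""

import math

import numpy as np
import pytest

from adrmine.graph_core import canonicalize
from adrmine.mining import (
    CLASS,
    NODE,
    TOP_ELEMENT,
    ConfigurationError,
    DomainVocabulary,
    FeatureRecord,
    MiningConfig,
    NeighborFeature,
    PathFeature,
    domain_filter,
    enumerate_paths,
    generalize_path,
    is_more_specific,
    mine_features,
    reachable_neighbors,
    specificity_filter,
    support_filter,
)

from conftest import build_graph
from oracle import (
    generalizer_oracle,
    mine_oracle,
    neighbors_oracle,
    patterns_oracle,
    random_config,
    random_graph,
    random_vocab,
    walks_oracle,
)


def path(*steps):
    return PathFeature(tuple((p, (NODE, n)) for p, n in steps))


NO_FILTER = MiningConfig(k=3, t=1, deg=-1, s_min=0, m="no-check")


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            MiningConfig(k=0)
        with pytest.raises(ConfigurationError):
            MiningConfig(s_min=6, s_max=2)
        with pytest.raises(ConfigurationError):
            MiningConfig(m="xyz")


class TestNeighbors:
    def test_isolated_root_has_empty_set(self):
        cg = canonicalize(build_graph(property_edges=[("a", "p", "b")]))
        cg.graph.entity_nodes.add("d")
        assert reachable_neighbors(cg, ["d"], NO_FILTER)["d"] == set()

    def test_chain_bounded_by_k(self, chain_cg):
        cfg = MiningConfig(k=2, deg=-1, s_min=0, m="no-check")
        result = reachable_neighbors(chain_cg, ["d"], cfg)["d"]
        assert result == {NeighborFeature("a"), NeighborFeature("b")}

    def test_hub_recorded_but_not_expanded(self):
        edges = [("d", "p", "h")] + [("h", "q", f"t{i}") for i in range(6)]
        cg = canonicalize(build_graph(property_edges=edges))
        cfg = MiningConfig(k=3, deg=5, s_min=0, m="no-check")
        result = reachable_neighbors(cg, ["d"], cfg)["d"]
        assert result == {NeighborFeature("h")}

    def test_absent_root_warns_and_is_empty(self, chain_cg):
        with pytest.warns(UserWarning, match="absent"):
            result = reachable_neighbors(chain_cg, ["ghost"], NO_FILTER)
        assert result["ghost"] == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_k_and_deg(self, seed):
        rng = np.random.default_rng(100 + seed)
        cg = canonicalize(random_graph(rng))
        roots = sorted(cg.graph.entity_nodes)[:3]
        prev_k: set = set()
        for k in (1, 2, 3):
            cfg = MiningConfig(k=k, deg=4, s_min=0, m="no-check")
            now = set().union(*reachable_neighbors(cg, roots, cfg).values())
            assert prev_k <= now
            prev_k = now
        prev_d: set = set()
        for deg in (2, 4, 8, -1):
            cfg = MiningConfig(k=3, deg=deg, s_min=0, m="no-check")
            now = set().union(*reachable_neighbors(cg, roots, cfg).values())
            assert prev_d <= now
            prev_d = now


class TestPaths:
    def test_shared_edge_pools_support(self):
        cg = canonicalize(build_graph(property_edges=[("d1", "p", "g"), ("d2", "p", "g")]))
        cfg = MiningConfig(k=1, deg=-1, s_min=0, m="no-check")
        result = enumerate_paths(cg, ["d1", "d2"], cfg)
        assert result == {path(("p", "g")): frozenset({"d1", "d2"})}

    def test_chain_yields_all_prefixes_up_to_k(self, chain_cg):
        cfg = MiningConfig(k=2, deg=-1, s_min=0, m="no-check")
        result = enumerate_paths(chain_cg, ["d"], cfg)
        assert set(result) == {path(("p", "a")), path(("p", "a"), ("q", "b"))}

    def test_blacklisted_predicate_never_traversed(self):
        cg = canonicalize(build_graph(property_edges=[("d", "p", "g"), ("g", "q", "w")]))
        cfg = MiningConfig(k=2, deg=-1, s_min=0, m="no-check", b_predicates=frozenset({"p"}))
        assert enumerate_paths(cg, ["d"], cfg) == {}

    def test_blacklisted_type_blocks_entry(self):
        g = build_graph(
            property_edges=[("d", "p", "x"), ("x", "q", "y")],
            instantiation=[("x", "Cbad")],
        )
        cfg = MiningConfig(
            k=2, deg=-1, s_min=0, m="no-check", b_exp_types=frozenset({"Cbad"})
        )
        assert enumerate_paths(canonicalize(g), ["d"], cfg) == {}

    def test_support_anti_monotone_along_prefixes(self):
        rng = np.random.default_rng(7)
        cg = canonicalize(random_graph(rng))
        roots = sorted(cg.graph.entity_nodes)[:5]
        cfg = MiningConfig(k=3, deg=-1, s_min=0, m="no-check")
        result = enumerate_paths(cg, roots, cfg)
        for feat, support in result.items():
            for cut in range(1, len(feat.steps)):
                prefix = PathFeature(feat.steps[:cut])
                assert support <= result[prefix]


class TestGeneralization:
    def test_two_node_path_with_one_class_each_gives_eight_patterns(self):
        g = build_graph(
            property_edges=[("d", "p1", "n1"), ("n1", "p2", "n2")],
            instantiation=[("n1", "C1"), ("n2", "C2")],
        )
        cg = canonicalize(g)
        patterns = generalize_path(path(("p1", "n1"), ("p2", "n2")), cg, NO_FILTER)
        n1, n2 = (NODE, "n1"), (NODE, "n2")
        c1, c2, top = (CLASS, "C1"), (CLASS, "C2"), TOP_ELEMENT
        expected = {
            PathFeature((("p1", a), ("p2", b)))
            for a, b in [
                (c1, n2), (n1, c2), (c1, c2), (top, n2),
                (n1, top), (c1, top), (top, c2), (top, top),
            ]
        }
        assert patterns == expected
        assert len(patterns) == (1 + 2) * (1 + 2) - 1

    def test_untyped_node_generalizes_to_top_only(self):
        cg = canonicalize(build_graph(property_edges=[("d", "p", "n")]))
        patterns = generalize_path(path(("p", "n")), cg, NO_FILTER)
        assert patterns == {PathFeature((("p", TOP_ELEMENT),))}

    def test_generalization_depth_counts_instantiation_as_one_step(self):
        g = build_graph(
            property_edges=[("d", "p", "n")],
            instantiation=[("n", "C")],
            subsumption=[("C", "Cp"), ("Cp", "Cpp")],
        )
        cg = canonicalize(g)
        cfg = MiningConfig(k=1, t=2, deg=-1, s_min=0, m="no-check")
        patterns = generalize_path(path(("p", "n")), cg, cfg)
        classes = {el[1] for pat in patterns for _, el in pat.steps if el[0] == CLASS}
        assert classes == {"C", "Cp"}  # Cpp is 3 steps away

    def test_blacklisted_generalizer_excluded_but_traversed(self):
        g = build_graph(
            property_edges=[("d", "p", "n")],
            instantiation=[("n", "C")],
            subsumption=[("C", "Cmid"), ("Cmid", "Cfar")],
        )
        cg = canonicalize(g)
        cfg = MiningConfig(
            k=1, t=3, deg=-1, s_min=0, m="no-check", b_gen_types=frozenset({"Cmid"})
        )
        patterns = generalize_path(path(("p", "n")), cg, cfg)
        classes = {el[1] for pat in patterns for _, el in pat.steps if el[0] == CLASS}
        assert classes == {"C", "Cfar"}  # Cmid removed, but distance still runs through it

    @pytest.mark.parametrize("seed", range(6))
    def test_pattern_count_closed_form(self, seed):
        """|generalize_path| == prod(c_i + 2) - 1 with c_i admissible classes."""
        rng = np.random.default_rng(300 + seed)
        g = random_graph(rng)
        cg = canonicalize(g)
        cfg = random_config(rng, g)
        roots = sorted(cg.graph.entity_nodes)[:4]
        walks = set().union(*(walks_oracle(cg, r, cfg) for r in roots))
        for walk in sorted(walks)[:20]:
            feat = PathFeature(tuple((p, (NODE, n)) for p, n in walk))
            counts = [len(generalizer_oracle(cg, n, cfg)) for _, n in walk]
            expected = math.prod(c + 2 for c in counts) - 1
            assert len(generalize_path(feat, cg, cfg)) == expected


class TestSpecificity:
    def _cg(self):
        g = build_graph(
            property_edges=[("d", "p", "n1"), ("n1", "q", "n2")],
            instantiation=[("n1", "C1"), ("n2", "C2")],
            subsumption=[("C1", "C1sup")],
        )
        return canonicalize(g)

    def test_reflexive(self):
        cg = self._cg()
        f = path(("p", "n1"), ("q", "n2"))
        assert is_more_specific(f, f, cg)

    def test_node_below_its_class_and_top(self):
        cg = self._cg()
        concrete = path(("p", "n1"), ("q", "n2"))
        pattern = PathFeature((("p", (CLASS, "C1")), ("q", TOP_ELEMENT)))
        assert is_more_specific(concrete, pattern, cg)
        assert not is_more_specific(pattern, concrete, cg)

    def test_class_below_transitive_superclass(self):
        cg = self._cg()
        lower = PathFeature((("p", (CLASS, "C1")),))
        upper = PathFeature((("p", (CLASS, "C1sup")),))
        assert is_more_specific(lower, upper, cg)
        assert not is_more_specific(upper, lower, cg)

    def test_different_predicates_incomparable(self):
        cg = self._cg()
        f1 = path(("p", "n1"))
        f2 = path(("q", "n1"))
        assert not is_more_specific(f1, f2, cg) and not is_more_specific(f2, f1, cg)

    def test_equal_support_drops_generalization(self):
        cg = self._cg()
        concrete = path(("p", "n1"))
        pattern = PathFeature((("p", (CLASS, "C1")),))
        records = [
            FeatureRecord(concrete, frozenset({"d1", "d2"})),
            FeatureRecord(pattern, frozenset({"d1", "d2"})),
        ]
        kept = {r.feature for r in specificity_filter(records, cg)}
        assert kept == {concrete}

    def test_larger_pattern_support_keeps_both(self):
        cg = self._cg()
        concrete = path(("p", "n1"))
        pattern = PathFeature((("p", (CLASS, "C1")),))
        records = [
            FeatureRecord(concrete, frozenset({"d1"})),
            FeatureRecord(pattern, frozenset({"d1", "d2"})),
        ]
        kept = {r.feature for r in specificity_filter(records, cg)}
        assert kept == {concrete, pattern}

    def test_class_pattern_beats_top_pattern_on_equal_support(self):
        cg = self._cg()
        classes = PathFeature((("p", (CLASS, "C1")), ("q", (CLASS, "C2"))))
        tops = PathFeature((("p", TOP_ELEMENT), ("q", TOP_ELEMENT)))
        records = [
            FeatureRecord(classes, frozenset({"d"})),
            FeatureRecord(tops, frozenset({"d"})),
        ]
        kept = {r.feature for r in specificity_filter(records, cg)}
        assert kept == {classes}


class TestSupportAndDomainFilters:
    @pytest.mark.parametrize(
        "size,s_min,s_max,kept",
        [(4, 5, None, False), (5, 5, None, True), (9, 0, None, True), (9, 0, 8, False)],
    )
    def test_inclusive_bounds(self, size, s_min, s_max, kept):
        rec = FeatureRecord(NeighborFeature("n"), frozenset(f"d{i}" for i in range(size)))
        assert bool(support_filter([rec], s_min, s_max)) == kept

    def test_no_check_passes_everything(self, chain_cg):
        recs = [FeatureRecord(NeighborFeature("a"), frozenset({"d"}))]
        assert domain_filter(recs, "no-check", None, chain_cg) == recs

    def test_category_matching(self):
        g = build_graph(
            property_edges=[("d", "p", "http://go/0005783"), ("d", "p", "chem1")],
            instantiation=[("pw1", "PathwayClass")],
        )
        cg = canonicalize(g)
        vocab = DomainVocabulary(
            pathway_prefixes=(), pathway_classes=frozenset({"PathwayClass"}),
            gene_or_go_prefixes=("http://go/",), gene_or_go_classes=frozenset(),
            mesh_prefixes=("http://mesh/",), mesh_classes=frozenset(),
        )
        go_rec = FeatureRecord(path(("p", "http://go/0005783")), frozenset({"d"}))
        chem_rec = FeatureRecord(path(("p", "chem1")), frozenset({"d"}))
        pw_rec = FeatureRecord(NeighborFeature("pw1"), frozenset({"d"}))
        assert domain_filter([go_rec], "g", vocab, cg) == [go_rec]
        assert domain_filter([chem_rec], "pgm", vocab, cg) == []
        # entity matching through its type
        assert domain_filter([pw_rec], "p", vocab, cg) == [pw_rec]

    def test_empty_category_is_configuration_error(self, chain_cg):
        vocab = DomainVocabulary()
        with pytest.raises(ConfigurationError):
            domain_filter([], "p", vocab, chain_cg)


class TestMineFeatures:
    def test_empty_drug_set_gives_empty_table(self, chain_cg):
        assert len(mine_features(chain_cg, [], NO_FILTER)) == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        """Full pipeline equals the independent exhaustive enumerator on
        random graphs across the parameter grid."""
        rng = np.random.default_rng(1000 + seed)
        g = random_graph(rng)
        cg = canonicalize(g)
        cfg = random_config(rng, g)
        vocab = random_vocab(rng, g)
        nodes = sorted(cg.graph.entity_nodes)
        n_roots = min(len(nodes), int(rng.integers(2, 6)))
        roots = list(rng.choice(nodes, size=n_roots, replace=False))
        table = mine_features(cg, roots, cfg, vocab)
        mined = {r.feature: r.support for r in table.records}
        expected = mine_oracle(cg, roots, cfg, vocab)
        assert mined == expected
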