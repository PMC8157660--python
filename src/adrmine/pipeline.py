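"""Configuration parsing and pipeline orchestration.

A flat key-value configuration file (YAML mapping, one level) bundles
the mining parameters (k, t, deg, s_min, s_max, undirected, the three
blacklists, m, top_iri), the domain vocabulary, the learner parameters,
and the random-negative eligibility rule.  Defaults reproduce the best
published operating point (k=3, t=3, deg=500, s_min=5, s_max=+inf,
directed traversal, m=pgm); the vocabulary and eligibility defaults
match the synthetic generator's namespaces so that a freshly simulated
dataset runs unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import synthetic
from .graph_core import CanonicalGraph, canonicalize, read_rdf
from .matrix import LabeledDrugSet, to_binary_matrix
from .mining import (
    ConfigurationError,
    DomainVocabulary,
    FeatureTable,
    MiningConfig,
    mine_features,
)
from .robustness import Eligibility


@dataclass(frozen=True)
class LearnerParams:
    min_leaf: int = 5
    boost_rounds: int = 10
    n_folds: int = 10
    min_cover: int = 5
    optimize_rounds: int = 2


@dataclass
class PipelineConfig:
    mining: MiningConfig
    vocab: DomainVocabulary
    learner: LearnerParams
    eligibility: Eligibility


_LIST_KEYS = {
    "b_predicates",
    "b_exp_types",
    "b_gen_types",
    "vocab_pathway_prefixes",
    "vocab_pathway_classes",
    "vocab_gene_or_go_prefixes",
    "vocab_gene_or_go_classes",
    "vocab_mesh_prefixes",
    "vocab_mesh_classes",
    "eligibility_prefixes",
}
_INT_KEYS = {"k", "t", "deg", "s_min", "min_leaf", "boost_rounds", "n_folds", "min_cover", "optimize_rounds"}
_KNOWN_KEYS = (
    _LIST_KEYS
    | _INT_KEYS
    | {"s_max", "undirected", "m", "top_iri", "eligibility_drug_class", "eligibility_link_predicate"}
)


def _as_list(key: str, value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [v for v in (part.strip() for part in value.split(",")) if v]
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    raise ConfigurationError(f"key {key!r} expects a list of IRIs")


def parse_config(path: str | None = None) -> PipelineConfig:
    """Parse a flat configuration file; an absent or empty file yields
    the full defaults.  Unknown keys or out-of-domain values raise a
    ConfigurationError naming the key."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("configuration must be a flat key-value mapping")
        raw = loaded
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")

    def get_int(key: str, default: int) -> int:
        value = raw.get(key, default)
        try:
            return int(value)
        except (TypeError, ValueError):
            raise ConfigurationError(f"key {key!r} expects an integer, got {value!r}")

    s_max_raw = raw.get("s_max")
    if s_max_raw in (None, "inf", "+inf", ".inf"):
        s_max = None
    else:
        try:
            s_max = int(s_max_raw)
        except (TypeError, ValueError):
            raise ConfigurationError(f"key 's_max' expects an integer or +inf, got {s_max_raw!r}")

    undirected = raw.get("undirected", False)
    if not isinstance(undirected, bool):
        raise ConfigurationError(f"key 'undirected' expects a boolean, got {undirected!r}")

    default_mining = MiningConfig()
    mining = MiningConfig(
        k=get_int("k", 3),
        t=get_int("t", 3),
        deg=get_int("deg", 500),
        s_min=get_int("s_min", 5),
        s_max=s_max,
        undirected=undirected,
        b_predicates=frozenset(
            _as_list("b_predicates", raw["b_predicates"])
            if "b_predicates" in raw
            else default_mining.b_predicates
        ),
        b_exp_types=frozenset(_as_list("b_exp_types", raw.get("b_exp_types"))),
        b_gen_types=frozenset(_as_list("b_gen_types", raw.get("b_gen_types"))),
        m=str(raw.get("m", "pgm")),
        top_iri=str(raw.get("top_iri", default_mining.top_iri)),
    )

    default_vocab = synthetic.default_vocabulary()
    def vocab_field(key: str, default):
        if key in raw:
            return _as_list(key, raw[key])
        return default

    vocab = DomainVocabulary(
        pathway_prefixes=tuple(vocab_field("vocab_pathway_prefixes", default_vocab.pathway_prefixes)),
        pathway_classes=frozenset(vocab_field("vocab_pathway_classes", default_vocab.pathway_classes)),
        gene_or_go_prefixes=tuple(
            vocab_field("vocab_gene_or_go_prefixes", default_vocab.gene_or_go_prefixes)
        ),
        gene_or_go_classes=frozenset(
            vocab_field("vocab_gene_or_go_classes", default_vocab.gene_or_go_classes)
        ),
        mesh_prefixes=tuple(vocab_field("vocab_mesh_prefixes", default_vocab.mesh_prefixes)),
        mesh_classes=frozenset(vocab_field("vocab_mesh_classes", default_vocab.mesh_classes)),
    )

    learner = LearnerParams(
        min_leaf=get_int("min_leaf", 5),
        boost_rounds=get_int("boost_rounds", 10),
        n_folds=get_int("n_folds", 10),
        min_cover=get_int("min_cover", 5),
        optimize_rounds=get_int("optimize_rounds", 2),
    )

    eligibility = Eligibility(
        drug_class_iri=str(raw.get("eligibility_drug_class", synthetic.DRUG_CLASS)),
        namespace_prefixes=tuple(
            _as_list("eligibility_prefixes", raw["eligibility_prefixes"])
            if "eligibility_prefixes" in raw
            else (synthetic.DRUG_NS,)
        ),
        external_link_predicate=raw.get("eligibility_link_predicate", synthetic.P_X_PUBCHEM),
    )
    return PipelineConfig(mining=mining, vocab=vocab, learner=learner, eligibility=eligibility)


def serialize_config(config: PipelineConfig, path: str) -> None:
    """Write a configuration so that parse_config reads it back equal."""
    mining, vocab, learner, elig = config.mining, config.vocab, config.learner, config.eligibility
    data = {
        "k": mining.k,
        "t": mining.t,
        "deg": mining.deg,
        "s_min": mining.s_min,
        "s_max": "+inf" if mining.s_max is None else mining.s_max,
        "undirected": mining.undirected,
        "b_predicates": sorted(mining.b_predicates),
        "b_exp_types": sorted(mining.b_exp_types),
        "b_gen_types": sorted(mining.b_gen_types),
        "m": mining.m,
        "top_iri": mining.top_iri,
        "vocab_pathway_prefixes": list(vocab.pathway_prefixes),
        "vocab_pathway_classes": sorted(vocab.pathway_classes),
        "vocab_gene_or_go_prefixes": list(vocab.gene_or_go_prefixes),
        "vocab_gene_or_go_classes": sorted(vocab.gene_or_go_classes),
        "vocab_mesh_prefixes": list(vocab.mesh_prefixes),
        "vocab_mesh_classes": sorted(vocab.mesh_classes),
        "min_leaf": learner.min_leaf,
        "boost_rounds": learner.boost_rounds,
        "n_folds": learner.n_folds,
        "min_cover": learner.min_cover,
        "optimize_rounds": learner.optimize_rounds,
        "eligibility_drug_class": elig.drug_class_iri,
        "eligibility_prefixes": list(elig.namespace_prefixes),
        "eligibility_link_predicate": elig.external_link_predicate,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def load_canonical_graph(paths: list[str], dialect: str = "ntriples") -> CanonicalGraph:
    return canonicalize(read_rdf(paths, dialect=dialect))


def canonical_labels(labeled: LabeledDrugSet, cg: CanonicalGraph) -> LabeledDrugSet:
    """Map drug IRIs through the canonical representatives."""
    out = LabeledDrugSet()
    for drug, label in labeled.assignments.items():
        out.assignments[cg.rep(drug)] = label
        out.provenance[cg.rep(drug)] = labeled.provenance.get(drug, "")
    return out


def mine_matrix(
    cg: CanonicalGraph,
    labeled: LabeledDrugSet,
    config: PipelineConfig,
) -> tuple[FeatureTable, "object"]:
    table = mine_features(cg, labeled.drugs(), config.mining, config.vocab)
    return table, to_binary_matrix(table, labeled)


def write_provenance(out_dir: str, config: PipelineConfig, seed: int, extra: dict | None = None) -> None:
    """Record the full parameter set and seed alongside the artifacts."""
    record = {
        "seed": seed,
        "mining": {
            **{
                key: (sorted(value) if isinstance(value, frozenset) else value)
                for key, value in asdict(config.mining).items()
            }
        },
        "learner": asdict(config.learner),
        "eligibility": {
            "drug_class_iri": config.eligibility.drug_class_iri,
            "namespace_prefixes": list(config.eligibility.namespace_prefixes),
            "external_link_predicate": config.eligibility.external_link_predicate,
        },
    }
    if extra:
        record.update(extra)
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=sorted), encoding="utf-8")
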