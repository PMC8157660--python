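"""Synthetic RDF knowledge graphs with planted, known structure.

The generator emulates the aspects of a real pharmacogenomic knowledge
graph that the mining pipeline must cope with: a class hierarchy under a
single top class, drug nodes duplicated across sources and joined by
owl:sameAs, hub nodes of very high degree, background edges to shared
entities, and — the ground truth — short discriminative paths
("signatures", e.g. drug →hasTarget gene →participatesIn pathway)
carried preferentially by positive drugs.

Each signature is carried independently by a POS drug with probability
``p_signal_pos`` and by a NEG drug with ``p_signal_neg``.  A single
binary signal caps the achievable out-of-sample AUC at
``p⊕(1−p⊖) + (p⊕p⊖ + (1−p⊕)(1−p⊖))/2`` (0.90 at the 0.9/0.1 defaults),
so the generator plants ``n_signatures`` independent signatures
(default 3, Bayes AUC ≈ 0.99) to make near-perfect recovery possible;
the first signature is the primary planted feature reported in the
ground truth.

Besides the labeled drugs, a pool of background drug nodes (typed with
the drug class, carrying the external-link predicate, but no signature)
is generated so that random-negative draws have a population to sample
from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_core import Graph, OWL_THING
from .matrix import DrugAttributes, LabeledDrugSet, NEG, POS
from .mining import NODE, DomainVocabulary, PathFeature
from .robustness import Eligibility

NS = "http://example.org/"
CLS = NS + "class/"
DRUG_NS = NS + "drug/"
GENE_NS = NS + "gene/"
PATHWAY_NS = NS + "pathway/"
GO_NS = NS + "go/"
MESH_NS = NS + "mesh/"
ENTITY_NS = NS + "entity/"
HUB_NS = NS + "hub/"
PUBCHEM_NS = NS + "pubchem/"
PRED = NS + "p/"

P_HAS_TARGET = PRED + "hasTarget"
P_PARTICIPATES = PRED + "participatesIn"
P_ASSOCIATED = PRED + "associatedWith"
P_PART_OF = PRED + "partOf"
P_X_PUBCHEM = PRED + "xPubchem"

DRUG_CLASS = CLS + "Drug"
APPROVED_DRUG_CLASS = CLS + "ApprovedDrug"
PATHWAY_CLASS = CLS + "Pathway"
ENTITY_CLASS = CLS + "Entity"


class GenerationError(Exception):
    """The synthetic specification is invalid."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic dataset.

    Defaults are the conditions the test suite and acceptance runs use:
    120 labeled drugs, three independently carried planted signatures at
    0.9 (positives) vs 0.1 (negatives), four background edges per drug,
    a depth-3 class hierarchy, 20% drug-node duplication, and hubs above
    the usual expansion cutoff of 500.
    """

    n_pos: int = 60
    n_neg: int = 60
    planted_signature: tuple[tuple[str, str], ...] | None = None
    n_signatures: int = 3
    p_signal_pos: float = 0.9
    p_signal_neg: float = 0.1
    background_edges_per_drug: float = 4.0
    hierarchy_depth: int = 3
    sameas_rate: float = 0.2
    n_hubs: int = 2
    hub_degree: int = 600
    n_background_drugs: int = 150
    n_background_entities: int = 80
    signature_through_hub: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_signal_neg < self.p_signal_pos <= 1.0):
            raise GenerationError(
                "need 0 <= p_signal_neg < p_signal_pos <= 1, got "
                f"{self.p_signal_neg} / {self.p_signal_pos}"
            )
        if self.planted_signature is not None and not (
            1 <= len(self.planted_signature) <= 3
        ):
            raise GenerationError("planted signature must have length 1..3")
        if self.n_signatures < 1:
            raise GenerationError("need at least one planted signature")


@dataclass
class GroundTruth:
    """Planted features (primary first) with their carrier sets."""

    planted: list[tuple[PathFeature, frozenset[str]]]

    @property
    def primary_feature(self) -> PathFeature:
        return self.planted[0][0]

    @property
    def primary_carriers(self) -> frozenset[str]:
        return self.planted[0][1]


def default_vocabulary() -> DomainVocabulary:
    """Domain vocabulary matching the generator's namespaces."""
    mesh_classes = frozenset({MESH_NS + f"M{i}" for i in range(10)})
    go_classes = frozenset({GO_NS + f"GO_{i}" for i in range(10)})
    return DomainVocabulary(
        pathway_prefixes=(PATHWAY_NS,),
        pathway_classes=frozenset({PATHWAY_CLASS}),
        gene_or_go_prefixes=(GENE_NS, GO_NS),
        gene_or_go_classes=go_classes,
        mesh_prefixes=(MESH_NS,),
        mesh_classes=mesh_classes,
    )


def default_eligibility(labeled: LabeledDrugSet) -> Eligibility:
    """Random-negative eligibility: drug-typed, drug-namespace nodes with
    an external structure link, excluding the expert-classified drugs."""
    return Eligibility(
        drug_class_iri=DRUG_CLASS,
        namespace_prefixes=(DRUG_NS,),
        external_link_predicate=P_X_PUBCHEM,
        excluded=frozenset(labeled.assignments),
    )


def _default_signature(j: int) -> tuple[tuple[str, str], ...]:
    return (
        (P_HAS_TARGET, GENE_NS + f"target{j}"),
        (P_PARTICIPATES, PATHWAY_NS + f"pw{j}"),
    )


def generate_kg(spec: SyntheticSpec) -> tuple[Graph, LabeledDrugSet, GroundTruth]:
    """Generate a graph, drug labels, and the planted ground truth.

    The same spec (including seed) always produces the same graph, down
    to byte-identical N-Triples serialization.
    """
    rng = np.random.default_rng(spec.seed)
    g = Graph()

    # --- class hierarchy under a single (virtual) top class -------------
    depth = max(1, spec.hierarchy_depth)
    chains = {
        "drug": [DRUG_CLASS] + [CLS + f"DrugL{i}" for i in range(1, depth)],
        "go": [GO_NS + f"GO_{i}" for i in range(depth)],
        "mesh": [MESH_NS + f"M{i}" for i in range(depth)],
    }
    for chain in chains.values():
        for lower, upper in zip(chain, chain[1:]):
            g.subsumption_edges.add((lower, upper))
        g.class_nodes.update(chain)
    g.subsumption_edges.add((APPROVED_DRUG_CLASS, DRUG_CLASS))
    g.class_nodes.update({APPROVED_DRUG_CLASS, PATHWAY_CLASS, ENTITY_CLASS})

    def add_entity(iri: str, cls: str | None = None) -> None:
        g.entity_nodes.add(iri)
        if cls is not None:
            g.instantiation_edges.add((iri, cls))
            g.class_nodes.add(cls)

    # --- drugs -----------------------------------------------------------
    pos_drugs = [DRUG_NS + f"pos{i:03d}" for i in range(spec.n_pos)]
    neg_drugs = [DRUG_NS + f"neg{i:03d}" for i in range(spec.n_neg)]
    bg_drugs = [DRUG_NS + f"bg{i:03d}" for i in range(spec.n_background_drugs)]
    labeled = LabeledDrugSet()
    for d in pos_drugs:
        labeled.assignments[d] = POS
        labeled.provenance[d] = "synthetic positive"
    for d in neg_drugs:
        labeled.assignments[d] = NEG
        labeled.provenance[d] = "synthetic negative"
    all_drugs = pos_drugs + neg_drugs + bg_drugs
    for i, d in enumerate(all_drugs):
        # alternate direct and indirect (subclass) drug typing
        add_entity(d, DRUG_CLASS if i % 2 == 0 else APPROVED_DRUG_CLASS)
        cid = PUBCHEM_NS + f"CID{i:05d}"
        add_entity(cid)
        g.property_edges.add((d, P_X_PUBCHEM, cid))

    # --- planted signatures ---------------------------------------------
    signatures: list[tuple[tuple[str, str], ...]] = []
    for j in range(spec.n_signatures):
        if j == 0 and spec.planted_signature is not None:
            signatures.append(tuple(spec.planted_signature))
        else:
            signatures.append(_default_signature(j))
    for sig in signatures:
        nodes = [n for _, n in sig]
        for node in nodes:
            if node.startswith(GENE_NS):
                add_entity(node, chains["go"][0])
            elif node.startswith(PATHWAY_NS):
                add_entity(node, PATHWAY_CLASS)
            else:
                add_entity(node, ENTITY_CLASS)
        for (_, src), (pred, dst) in zip(sig, sig[1:]):
            g.property_edges.add((src, pred, dst))

    carriers: list[set[str]] = [set() for _ in signatures]
    for d in pos_drugs + neg_drugs:
        p = spec.p_signal_pos if labeled.assignments[d] == POS else spec.p_signal_neg
        for j, sig in enumerate(signatures):
            if rng.random() < p:
                pred0, node0 = sig[0]
                g.property_edges.add((d, pred0, node0))
                carriers[j].add(d)

    # --- background entities and edges ----------------------------------
    entities = [ENTITY_NS + f"e{i:03d}" for i in range(spec.n_background_entities)]
    entity_classes = [chains["mesh"][0], chains["go"][0], ENTITY_CLASS]
    for i, e in enumerate(entities):
        add_entity(e, entity_classes[i % len(entity_classes)])
    if entities:
        for e in entities:
            for _ in range(int(rng.integers(1, 3))):
                other = entities[int(rng.integers(0, len(entities)))]
                if other != e:
                    g.property_edges.add((e, P_PART_OF, other))
        for d in all_drugs:
            n_edges = int(rng.poisson(spec.background_edges_per_drug))
            for _ in range(n_edges):
                e = entities[int(rng.integers(0, len(entities)))]
                g.property_edges.add((d, P_ASSOCIATED, e))

    # --- hubs -------------------------------------------------------------
    hub_nodes = [HUB_NS + f"h{i}" for i in range(spec.n_hubs)]
    for hi, hub in enumerate(hub_nodes):
        add_entity(hub, ENTITY_CLASS)
        for i in range(spec.hub_degree):
            filler = HUB_NS + f"h{hi}_n{i:04d}"
            add_entity(filler, ENTITY_CLASS)
            g.property_edges.add((hub, P_ASSOCIATED, filler))
        for d in all_drugs:
            if rng.random() < 0.3:
                g.property_edges.add((d, P_ASSOCIATED, hub))
    if spec.signature_through_hub and signatures:
        # make the primary signature's first intermediate node a hub
        first_node = signatures[0][0][1]
        for i in range(spec.hub_degree):
            filler = HUB_NS + f"sig_n{i:04d}"
            add_entity(filler, ENTITY_CLASS)
            g.property_edges.add((first_node, P_ASSOCIATED, filler))

    # --- sameAs duplicates ------------------------------------------------
    for d in pos_drugs + neg_drugs:
        if rng.random() < spec.sameas_rate:
            dup = d + "_alt"  # lexicographically after d: d stays representative
            add_entity(dup)
            g.identity_pairs.add(frozenset((d, dup)))
            out_edges = sorted(e for e in g.property_edges if e[0] == d)
            for edge in out_edges:
                if rng.random() < 0.5:
                    g.property_edges.discard(edge)
                    g.property_edges.add((dup, edge[1], edge[2]))

    # --- labels ------------------------------------------------------------
    for d in pos_drugs + neg_drugs + bg_drugs:
        g.add_label(d, "Drug " + d.rsplit("/", 1)[-1])
    for sig in signatures:
        for _, node in sig:
            g.add_label(node, node.rsplit("/", 1)[-1].capitalize())

    planted = [
        (
            PathFeature(tuple((p, (NODE, n)) for p, n in sig)),
            frozenset(carriers[j]),
        )
        for j, sig in enumerate(signatures)
    ]
    return g, labeled, GroundTruth(planted=planted)


def make_attributes(labeled: LabeledDrugSet, g: Graph) -> DrugAttributes:
    """Attribute table (external id, SMILES, synonyms) for all drug nodes."""
    attrs = DrugAttributes()
    drug_nodes = sorted(n for n in g.entity_nodes if n.startswith(DRUG_NS) and not n.endswith("_alt"))
    for i, d in enumerate(drug_nodes):
        local = d.rsplit("/", 1)[-1]
        attrs.external_id[d] = f"CID{i:05d}"
        attrs.smiles[d] = "C" * ((i % 5) + 1)
        attrs.synonyms[d] = (f"Drug {local}", local.upper())
    return attrs


def write_dataset(spec: SyntheticSpec, out_dir: str) -> dict[str, str]:
    """Generate and write the N-Triples graph plus companion TSVs.

    Returns the paths written: graph, labels, attributes.
    """
    from .graph_core import write_ntriples

    g, labeled, truth = generate_kg(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph_path = str(out / "kg.nt")
    labels_path = str(out / "labels.tsv")
    attrs_path = str(out / "attributes.tsv")
    write_ntriples(g, graph_path)
    with open(labels_path, "w", encoding="utf-8") as handle:
        handle.write("drug_iri\tlabel\tprovenance\n")
        for d in labeled.drugs():
            handle.write(f"{d}\t{labeled.assignments[d]}\t{labeled.provenance[d]}\n")
    make_attributes(labeled, g).write_tsv(attrs_path)
    return {"graph": graph_path, "labels": labels_path, "attributes": attrs_path}


def read_labels_tsv(path: str) -> LabeledDrugSet:
    labeled = LabeledDrugSet()
    with open(path, encoding="utf-8") as handle:
        handle.readline()
        for line in handle:
            drug, label, provenance = line.rstrip("\n").split("\t")
            labeled.assignments[drug] = label
            labeled.provenance[drug] = provenance
    return labeled
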