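"""Robustness protocols: label shuffling, random negatives, overlaps.

Two controls probe what the classifiers actually learn.  Shuffling the
class assignment destroys any real signal, so a sound pipeline should
fall to chance-level AUC.  Replacing the expert-chosen negatives with
drugs drawn at random from the knowledge graph tests how much of the
difficulty comes from expert negatives resembling positives; the draw
is repeated five times and the stability of the selected features is
summarized by counting features present in exactly 5, 4, 3, or 2 of the
five selections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph_core import CanonicalGraph
from .matrix import NEG, POS, LabeledDrugSet
from .mining import index_of


def shuffle_labels(labeled: LabeledDrugSet, seed: int = 0) -> LabeledDrugSet:
    """Permute the labels across drugs, preserving the class multiset."""
    drugs = labeled.drugs()
    values = [labeled.assignments[d] for d in drugs]
    rng = np.random.default_rng(seed)
    permuted = [values[i] for i in rng.permutation(len(values))]
    out = LabeledDrugSet()
    for drug, label in zip(drugs, permuted):
        out.assignments[drug] = label
        out.provenance[drug] = "shuffled"
    return out


@dataclass(frozen=True)
class Eligibility:
    """Which graph nodes qualify as random negative candidates.

    A node is eligible iff it instantiates (directly or through subclass
    edges) ``drug_class_iri``, its IRI starts with one of
    ``namespace_prefixes`` (if any are given), it has an outgoing
    ``external_link_predicate`` edge (if given — the proxy for having a
    structure description), and it is not among the excluded drugs.
    """

    drug_class_iri: str
    namespace_prefixes: tuple[str, ...] = ()
    external_link_predicate: str | None = None
    excluded: frozenset[str] = frozenset()


def eligible_pool(cg: CanonicalGraph, eligibility: Eligibility) -> list[str]:
    idx = index_of(cg)
    pool = []
    for node in sorted(cg.graph.entity_nodes):
        if node in eligibility.excluded:
            continue
        if eligibility.drug_class_iri not in idx.type_closure(node):
            continue
        if eligibility.namespace_prefixes and not any(
            node.startswith(p) for p in eligibility.namespace_prefixes
        ):
            continue
        if eligibility.external_link_predicate is not None and not any(
            p == eligibility.external_link_predicate for p, _ in idx.out.get(node, ())
        ):
            continue
        pool.append(node)
    return pool


def draw_random_negatives(
    cg: CanonicalGraph,
    positives: Iterable[str],
    n: int,
    eligibility: Eligibility,
    seed: int = 0,
) -> LabeledDrugSet:
    """Sample n eligible nodes without replacement as the negative class.

    Positives keep their POS label; drawn nodes are labeled NEG.  The
    positives and all excluded drugs are never drawn.
    """
    positives = sorted(set(positives))
    elig = Eligibility(
        drug_class_iri=eligibility.drug_class_iri,
        namespace_prefixes=eligibility.namespace_prefixes,
        external_link_predicate=eligibility.external_link_predicate,
        excluded=eligibility.excluded | frozenset(positives),
    )
    pool = eligible_pool(cg, elig)
    if len(pool) < n:
        raise ValueError(f"eligible pool has {len(pool)} nodes, cannot draw {n}")
    rng = np.random.default_rng(seed)
    drawn = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    out = LabeledDrugSet()
    for drug in positives:
        out.assignments[drug] = POS
        out.provenance[drug] = "expert positive"
    for drug in drawn:
        out.assignments[drug] = NEG
        out.provenance[drug] = "random draw"
    return out


def feature_overlap(selected: Sequence[set[str]]) -> dict[int, int]:
    """Counts of features occurring in exactly 5, 4, 3 or 2 of five sets."""
    if len(selected) != 5:
        raise ValueError(f"expected exactly five feature sets, got {len(selected)}")
    occurrences: dict[str, int] = {}
    for s in selected:
        for f in s:
            occurrences[f] = occurrences.get(f, 0) + 1
    counts = {level: 0 for level in (5, 4, 3, 2)}
    for mult in occurrences.values():
        if mult in counts:
            counts[mult] += 1
    return counts


def random_negative_seeds(seed: int, n_draws: int = 5) -> list[int]:
    """Draw i (1..n) uses seed + i, so the protocol is reproducible."""
    return [seed + i for i in range(1, n_draws + 1)]
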