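# adrmine

Knowledge-graph feature mining and explainable classification of drugs
causative — or not — for adverse drug reactions (ADRs).

Most ADRs, including the commonly monitored hepatic (DILI, drug-induced
liver injury) and cutaneous (SCAR, severe cutaneous adverse reaction)
toxicities, have unknown molecular mechanisms.  Expert classifications
label drugs as causative or not for these ADRs, and open biomedical
knowledge graphs (drugs, targets, pathways, GO and MeSH terms) describe
what is known about each drug.  `adrmine` mines such an RDF knowledge
graph for binary drug features and trains deliberately simple,
human-readable classifiers on them: if an interpretable feature helps
reproduce the expert classification, it is a candidate element of the
ADR's mechanism.  The intended users are bioinformaticians and
pharmacovigilance researchers who want explanations, not just
predictions.

## Method

1. **Canonicalization.** Nodes linked by `owl:sameAs` represent the same
   entity across sources; their connected components are contracted into
   single nodes pooling all edges.
2. **Feature mining.** For each drug *d* in the labeled set *D*, three
   kinds of binary features are enumerated within distance *k*:
   - *neighbors*: any node reachable from *d* in ≤ *k* hops (distance-free);
   - *paths*: sequences *d* →p₁ n₁ →p₂ n₂ … of length ≤ *k*;
   - *path patterns*: paths with positions generalized to an ontology
     class ≤ *t* instantiation/subsumption steps from the node, or to the
     top class ⊤ (always admissible).  A length-2 path with one class per
     node yields (1+2)·(1+2) − 1 = 8 patterns.

   Filters keep the space tractable: predicate and entity-type
   blacklists; a hub cutoff *deg* (nodes with more than *deg* incident
   edges are reachable but never expanded); inclusive support bounds
   [s_min, s_max] on the number of drugs carrying a feature; a
   most-specific filter that, among features carried by exactly the same
   drugs, keeps only those not generalized by another; and a domain
   filter *m* keeping features that mention a pathway (p), gene/GO term
   (g), or MeSH term (m), in any disjunction.  Defaults: *k*=3, *t*=3,
   *deg*=500, s_min=5, s_max=+∞, directed traversal, *m*=pgm.
3. **Learning.** The drug × feature matrix is binary.  Per fold of a
   10-fold cross-validation, a wrapper feature selection boosts up to 10
   CART trees (Gini, all features per split, ≥ 5 examples per leaf,
   class-balanced instance weights; early stop on perfect fit) and keeps
   every feature used by any tree; a final tree on the selected features
   is scored on the held-out drugs (precision, recall, F1 for the
   positive class, accuracy, AUC-ROC).  A sequential-covering (RIPPER
   style) learner produces ordered rules ⋀a ∧ ⋀¬b ⇒ ⊕ over the same
   features, each rule covering ≥ 5 training instances.
4. **Robustness and interpretation.** Controls: label shuffling (should
   fall to chance AUC) and five draws of random negatives from the
   graph's drug population (should be easier than expert negatives),
   with feature-overlap counts across the five selections.  For expert
   review, rule features are stripped of patterns made only of generic
   classes, rendered via `rdfs:label`, and 3-rater YES/MAYBE/NO answers
   are summarized by mean pairwise Cohen's κ and positivity ratios.

A synthetic generator emulates the relevant structure of a real
pharmacogenomic graph — class hierarchies, `owl:sameAs` duplicates,
hubs, background edges — and plants discriminative paths carried
preferentially by positive drugs, so the whole pipeline is testable
without external data.

## Worked example

```python
from adrmine import (SyntheticSpec, generate_kg, canonicalize, MiningConfig,
                     mine_features, to_binary_matrix, cross_validate,
                     serialize_feature, boosted_selection)
from adrmine.synthetic import default_vocabulary

spec = SyntheticSpec(seed=1)                      # 60 positives, 60 negatives
graph, labels, truth = generate_kg(spec)
cg = canonicalize(graph)                          # contract owl:sameAs duplicates
cfg = MiningConfig()                              # k=3, t=3, deg=500, s_min=5, m="pgm"
table = mine_features(cg, labels.drugs(), cfg, default_vocabulary())
print(f"{len(table)} features mined from {graph.n_triples()} triples")

matrix = to_binary_matrix(table, labels)
report = cross_validate(matrix, labels, n_folds=10, seed=1)
m = report.mean
print(f"mean precision={m.precision:.2f} recall={m.recall:.2f} "
      f"f1={m.f1:.2f} accuracy={m.accuracy:.2f} auc={m.auc:.2f}")

selected = boosted_selection(matrix.data, matrix.labels_vector(labels), seed=1)
planted = serialize_feature(truth.primary_feature, cfg.top_iri)
print("planted path selected:", planted in {matrix.feature_ids[j] for j in selected})
```

prints

```
472 features mined from 4617 triples
mean precision=0.85 recall=0.79 f1=0.80 accuracy=0.82 auc=0.92
planted path selected: True
```

The cross-validated tree reproduces the synthetic "expert"
classification well above chance (AUC 0.92 for this seed), and the
planted discriminative path (drug →hasTarget gene →participatesIn
pathway) is among the boosting-selected features — exactly the kind of
human-readable candidate explanation the method is after.

The same pipeline is available from the shell:

```sh
adrmine simulate --out-dir data --seed 1
adrmine crossval --graph data/kg.nt --labels data/labels.tsv --out-dir out --seed 1
adrmine rules    --graph data/kg.nt --labels data/labels.tsv --out-dir out --seed 1
```

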