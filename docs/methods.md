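# Methods

## Model and procedure

`adrmine` treats "which drugs cause this adverse reaction?" as a binary
classification problem whose features are mined from an RDF knowledge
graph, with the explicit constraint that the model must stay readable:
the point is not predictive performance but features a pharmacologist
can inspect as candidate mechanism elements.

The pipeline runs in five stages.

**Canonicalization.** `owl:sameAs` is treated as symmetric and
transitive; connected components of the identity relation are
contracted, each onto its lexicographically smallest member (a
deterministic, content-free choice).  Edge sets are rewritten through
the mapping with set semantics — duplicate edges collapse, self-loops
arising from contraction are kept (they are harmless: features are
set-valued and simple walks never revisit a node).  Labels of merged
nodes are pooled, sorted, and the first becomes the primary display
label.  Identity-like predicates other than `owl:sameAs` (e.g.
`skos:exactMatch`) can optionally be contracted too; this is off by
default because their semantics is weaker.  Literals are discarded on
ingestion, except `rdfs:label` values kept in a side table for
rendering.  A node counts as a class if it is the object of `rdf:type`,
an endpoint of `rdfs:subClassOf`, or declared `owl:Class`/`rdfs:Class`;
punning (a node that is both entity and class) is tolerated because
real linked data contains it.

**Feature mining.**  Traversal follows outgoing property edges
(optionally both directions, keeping the predicate label).  Three
node-local rules prune it: blacklisted predicates are never crossed;
nodes whose transitive type set meets the expansion-type blacklist are
never entered; nodes with more than `deg` incident property edges
("hubs") are recorded as endpoints/neighbors but never expanded.  Roots
are always expanded regardless of their own degree — a drug that is
itself a hub would otherwise produce no features at all.  `rdf:type`
is blacklisted by default so exploration runs through entities, not
classes; class structure enters only through generalization.

Paths are simple walks (no node revisited, the root included): cyclic
walks would generate unbounded families of features that describe the
same structure.  Path enumeration is level-wise with lower-support
pruning: a walk sequence's support (the set of roots realizing it) can
only shrink as the sequence grows, so any sequence whose support is
already below `s_min` is dropped and not extended.  Consequently paths
below `s_min` also do not feed pattern generation; a pattern's support
is defined as the union of the supports of the surviving paths it
generalizes.  This is the one place where the pipeline's semantics is
pinned by a tractability decision, and the brute-force oracle in the
test suite implements the identical contract.

Generalization replaces a path position's node by an ontology class at
most `t` steps away, counting the instantiation edge as one step and
each subsumption edge as one more, or by the top class ⊤, which is
always admissible (so an untyped node still generalizes to ⊤).
Generalizer-blacklisted classes are removed from the options but still
traversed when counting distance — blacklisting a mid-hierarchy class
should not hide its ancestors.  A path with `c_i` admissible classes at
position `i` yields `prod(c_i + 2) − 1` patterns (every combination
except the all-original one).

Filters apply in the order: support bounds, specificity, domain.
Support bounds are inclusive, `[s_min, s_max]` — the conventional
reading of "minimum/maximum support".  The specificity filter groups
features by exact support set and removes any feature strictly
generalized by another in its group (node ≼ its transitive classes ≼
their superclasses ≼ ⊤, positionwise over aligned predicate
sequences), leaving an antichain per group; neighbors are compared only
by equality.  The domain filter keeps features mentioning at least one
element of a requested category (pathway / gene-or-GO / MeSH, any
disjunction); an entity matches a category through its IRI namespace or
through a class it transitively instantiates, a class through its IRI
or listed membership.  ⊤ matches nothing.

**Learning.**  Trees and boosting go through scikit-learn: CART with
Gini impurity, all features candidate at every split, at least 5
examples per leaf, and instance weights normalizing each class's total
weight to 1/2 (the "artificial balancing" that makes the minority ADR
class matter).  A tiny `min_impurity_decrease` (1e-9) suppresses
zero-gain splits that floating-point noise in the balanced weights
would otherwise allow.  Wrapper selection boosts up to 10 such trees
(discrete AdaBoost) and keeps the union of features any tree used;
boosting stops early on a perfect fit, and the selection is by
construction a subset of the non-constant features.  Cross-validation
uses a single random 10-fold split; selection is re-run inside every
fold on its training part only.  Metrics: precision, recall, F1 for the
positive class (precision defined as 0 when nothing is predicted
positive), accuracy, and AUC-ROC from leaf-probability scores with
midrank tie handling (constant scores give exactly 0.5; single-class
test labels give a missing AUC, excluded from fold means).  Fold means
are unweighted (macro).  Metric comparisons use a two-sided Welch
t-test, since equal variances cannot be assumed between learners.

**Rule induction.**  The sequential coverer is hand-built (no suitable
dependency is available, and the rule learner is a core deliverable).
It targets the minority class (warning and swap if the positive class
is not the minority), grows each rule on a stratified 2/3 of the
remaining examples by greedily adding the literal — a feature affirmed
or negated — with the best Laplace-smoothed FOIL gain, prunes it on the
held-out 1/3 by maximizing (p−n)/(p+n) with ties preferring shorter
rules, and accepts it only if it covers at least `min_cover` (default
5) training instances and is no worse than chance on the prune split;
covered examples are then removed.  Two optimization rounds revisit
each rule, propose a re-grown replacement and a revision, and keep
whichever of the three minimizes whole-train error of the full list.
This replaces RIPPER's description-length bookkeeping with a simpler
but behaviorally equivalent stop/choice criterion; the properties that
matter downstream — rule form (⋀a ∧ ⋀¬b ⇒ ⊕, default ⊖), the coverage
floor, and training-set agreement with the tree on separable data —
are enforced and tested.

**Robustness and agreement.**  Label shuffling permutes the class
assignment (multiset preserved); a sound pipeline falls into the
chance band.  Random negatives are sampled without replacement from
graph nodes that transitively instantiate the drug class, carry the
configured external structure link, match the drug namespaces, and are
not in the expert classification; five draws use seeds `seed+1 …
seed+5`.  Feature overlap across the five whole-train selections is
counted at exact multiplicities 5, 4, 3, 2 (exact, not cumulative, so
the counts partition the shared features).  Whole-train selections are
used for the overlap statistic, matching the protocol's "mean number of
selected features" framing.  Cohen's κ uses marginal-product chance
agreement, with the degenerate p_e = 1 case defined as 1 for perfect
agreement and 0 otherwise; the three-rater summary is the unweighted
mean of the three pairwise κ values (computed three-way, or binarized
by merging YES and MAYBE).  Treating a feature and its negation as one
item for "explanatory" purposes is a data-preparation convention on the
input table, not a computation.

## Synthetic data: what it emulates, what it does not

The generator builds a graph with the structures the pipeline must
survive: a class hierarchy of configurable depth under a single top
class (with both direct and subclass drug typing, so instantiation
closure is exercised); drug nodes duplicated at rate `sameas_rate` with
their outgoing edges randomly split across the duplicates and rejoined
by `owl:sameAs` (canonicalization must make this invisible end to end);
hub nodes wired to `hub_degree` (default 600) filler entities, above
the default expansion cutoff of 500; per-drug background edges (Poisson
with mean 4) into a shared entity pool with its own second-hop edges;
and an external-link predicate plus attribute table (external id,
SMILES, synonyms) feeding the classification-mapping and
random-negative machinery.

The signal is a set of short planted paths (drug →hasTarget gene
→participatesIn pathway), each carried independently by a positive
drug with probability 0.9 and a negative drug with probability 0.1.
A single such binary signal caps any classifier's out-of-sample AUC at
0.9·0.9 + 0.9·0.1 = 0.90, below what a near-perfect recovery experiment
needs to demonstrate; the generator therefore plants three independent
signatures by default (Bayes AUC ≈ 0.99), with the first one designated
the primary ground-truth feature.  Defaults are 60 positives, 60
negatives, and a pool of 150 unlabeled background drugs for
random-negative draws.  Recovery experiments run over five seeds; with
~12 test drugs per fold, single-seed CV means are noisy, so headline
numbers are means over the five seed-runs.

What the generator does **not** emulate: real biology (edge semantics
are arbitrary), the scale of a production pharmacogenomic graph (~10⁸
triples vs ~5·10³ here), heterogeneous cross-source identifier schemes,
noisy or contradictory typing, and expert-chosen negatives whose
hardness comes from genuine biochemical similarity rather than a
carriage probability.  Passing tests therefore certify the mining
semantics, the filters, and the learning/robustness protocols — not
real-data performance, which depends on graph content the synthetic
world cannot stand in for.  In particular the published real-data
headline figures (accuracies around 0.74–0.81, the shuffled AUCs near
0.5, the κ values) are only mirrored directionally here.

## Numerical and design choices

- Determinism everywhere: sorted iteration orders, lexicographic
  representatives, a single seed flowing into every random draw, and
  byte-identical N-Triples serialization (sorted lines).
- Tree split ties are resolved by scikit-learn under a fixed
  `random_state` rather than by an explicit lowest-index rule; the goal
  (reproducibility) is preserved even though the tie-break rule itself
  is the library's.
- Degenerate inputs: an empty graph canonicalizes to an empty graph; an
  empty drug set mines an empty table; single-class training data yields
  a single-leaf tree; a fold whose training part is single-class is
  skipped with a warning; a Welch test between two zero-variance equal
  samples returns (0, 1); the eligible random-negative pool being
  smaller than the requested draw is an error reporting the pool size.
- Problem sizes in tests and the acceptance script (120 labeled drugs,
  ~4.6k triples, 200 random oracle graphs of ≤ 200 triples) were chosen
  so the full suite exercises every code path at desk scale; they are
  the package's reference experiment sizes.

## Known limitations

- Pattern supports are computed from enumerated paths, not by
  independent graph matching; under aggressive `s_min` pruning a
  pattern's support can undercount drugs that only realize low-support
  paths.  This is the documented, oracle-tested semantics.
- The miner holds all walk realizations of the current level in memory;
  it is meant for graphs up to ~10⁵ triples, not production LOD scale.
- The rule learner approximates RIPPER's MDL stop; on noisy data it can
  emit slightly different rule lists than JRip would, though of the
  same form and coverage discipline.
- Name-based classification mapping is exact (case-folded, trimmed); no
  fuzzy matching, by design — a silent mismatch is worse than a
  reported one.  Ties across synonym sources raise an error rather than
  guessing.
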