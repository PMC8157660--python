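"""Feature rendering for expert review and inter-rater agreement.

Rule features are post-filtered to drop patterns made only of generic
classes (e.g. Resource, Drug, or ⊤), which experts cannot interpret,
then rendered into readable strings by resolving IRIs to labels.  Three
raters answer YES / MAYBE / NO to "is this feature explanatory for the
ADR?"; agreement is summarized by pairwise Cohen's kappa (three-way, or
binarized by merging YES and MAYBE) and by ratios of features on which
1, 2, or all 3 raters are positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mining import CLASS, NODE, TOP, Feature, NeighborFeature, PathFeature
from .rules import RuleModel

YES, MAYBE, NO = "YES", "MAYBE", "NO"
ANSWERS = (YES, MAYBE, NO)


def filter_generic_patterns(
    features: Sequence[Feature] | RuleModel,
    generic_classes: Iterable[str],
    feature_lookup: Mapping[int, Feature] | None = None,
) -> list[Feature]:
    """Distinct rule features, minus patterns that say nothing specific.

    A pattern is dropped when every generalized position is ⊤ or one of
    the listed generic classes.  Accepts either a feature sequence or a
    RuleModel plus a lookup from literal feature index to Feature.
    """
    generic = set(generic_classes)
    if isinstance(features, RuleModel):
        if feature_lookup is None:
            raise ValueError("a RuleModel needs a feature_lookup")
        ordered: list[Feature] = []
        for rule in features.rules:
            for j, _ in rule.literals:
                ordered.append(feature_lookup[j])
    else:
        ordered = list(features)
    kept: list[Feature] = []
    seen: set[Feature] = set()
    for feat in ordered:
        if feat in seen:
            continue
        seen.add(feat)
        if isinstance(feat, PathFeature) and feat.is_pattern:
            generalized = [el for _, el in feat.steps if el[0] != NODE]
            if all(el[0] == TOP or el[1] in generic for el in generalized):
                continue
        kept.append(feat)
    return kept


def _local_name(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            tail = iri.rstrip(sep).rsplit(sep, 1)[-1]
            if tail:
                return tail
    return iri


def render_feature(
    feature: Feature,
    labels: Mapping[str, str] | None = None,
    negated: bool = False,
    top_label: str = "Thing",
) -> str:
    """Human-readable rendering, resolving IRIs to labels.

    Unlabeled IRIs fall back to their local name (after the last '/' or
    '#'); a negated literal is rendered with a leading NOT.
    """
    labels = labels or {}
    resolve = lambda iri: labels.get(iri, _local_name(iri))
    if isinstance(feature, NeighborFeature):
        body = resolve(feature.node)
    else:
        parts = []
        for pred, (kind, iri) in feature.steps:
            shown = top_label if kind == TOP else resolve(iri)
            parts.append(f"→{resolve(pred)} {shown}")
        body = " ".join(parts)
    return f"NOT {body}" if negated else body


def cohens_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Chance agreement uses the product of marginals.  When p_e = 1 the
    statistic is defined as 1 for perfect agreement, else 0.
    """
    if len(a) != len(b):
        raise ValueError("annotation vectors must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty annotations")
    categories = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum(
        (sum(x == c for x in a) / n) * (sum(y == c for y in b) / n) for c in categories
    )
    if p_e >= 1.0 - 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return (p_o - p_e) / (1 - p_e)


@dataclass
class AgreementTable:
    """Per-feature answers of exactly three raters."""

    feature_ids: tuple[str, ...]
    answers: tuple[tuple[str, str, str], ...]  # one triple per feature

    def __post_init__(self):
        if len(self.feature_ids) != len(self.answers):
            raise ValueError("one answer triple per feature required")
        for triple in self.answers:
            if len(triple) != 3:
                raise ValueError("exactly three raters required")
            for ans in triple:
                if ans not in ANSWERS:
                    raise ValueError(f"answer must be one of {ANSWERS}, got {ans!r}")

    def rater(self, i: int) -> list[str]:
        return [triple[i] for triple in self.answers]

    @classmethod
    def read_tsv(cls, path: str) -> "AgreementTable":
        ids, answers = [], []
        with open(path, encoding="utf-8") as handle:
            handle.readline()  # header: feature_id, rater1..3
            for line in handle:
                row = line.rstrip("\n").split("\t")
                ids.append(row[0])
                answers.append((row[1].upper(), row[2].upper(), row[3].upper()))
        return cls(tuple(ids), tuple(answers))


def _binarize(values: Sequence[str]) -> list[str]:
    return [YES if v in (YES, MAYBE) else NO for v in values]


def average_pairwise_kappa(table: AgreementTable, binarize: bool = False) -> float:
    """Unweighted mean of the three pairwise kappas; binarizing merges
    YES and MAYBE into a single positive answer first."""
    kappas = []
    for i, j in combinations(range(3), 2):
        a, b = table.rater(i), table.rater(j)
        if binarize:
            a, b = _binarize(a), _binarize(b)
        kappas.append(cohens_kappa(a, b))
    return float(np.mean(kappas))


def agreement_summary(table: AgreementTable) -> dict[str, tuple[float, int]]:
    """Counts and ratios of features by rater positivity.

    A rater is positive on a feature when answering YES or MAYBE.
    Returns, per column, (ratio, count): full agreement on unexplanatory
    (all NO), at least 1 / 2 / 3 raters positive, and full agreement on
    explanatory (all YES).
    """
    n = len(table.feature_ids)
    if n == 0:
        raise ValueError("empty agreement table")
    pos_counts = [sum(ans in (YES, MAYBE) for ans in triple) for triple in table.answers]
    all_no = sum(all(ans == NO for ans in triple) for triple in table.answers)
    all_yes = sum(all(ans == YES for ans in triple) for triple in table.answers)
    out = {
        "agree_unexplanatory": (all_no / n, all_no),
        "agree_explanatory": (all_yes / n, all_yes),
    }
    for level in (1, 2, 3):
        count = sum(c >= level for c in pos_counts)
        out[f"positive_ge_{level}"] = (count / n, count)
    return out


def write_summary_tsv(table: AgreementTable, path: str) -> None:
    summary = agreement_summary(table)
    columns = [
        "agree_unexplanatory",
        "positive_ge_1",
        "positive_ge_2",
        "positive_ge_3",
        "agree_explanatory",
    ]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("column\tratio\tcount\n")
        for col in columns:
            ratio, count = summary[col]
            handle.write(f"{col}\t{ratio:.4f}\t{count}\n")
        handle.write(f"kappa_3way\t{average_pairwise_kappa(table, binarize=False):.4f}\t\n")
        handle.write(f"kappa_binary\t{average_pairwise_kappa(table, binarize=True):.4f}\t\n")
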