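"""Expert drug classifications and the binary learning matrix.

Two published expert classifications motivate the defaults here: a DILI
(drug-induced liver injury) concern ranking of FDA-approved drugs, and a
drug "notoriety" list for severe cutaneous adverse reactions (SCAR).
Raw entries carry a drug identifier or name plus a source class; they
are mapped onto canonical graph nodes (by external id, or by normalized
name against synonym lists), restricted to drugs with a SMILES structure
description, and relabeled POS/NEG through an explicit class map.

The learning view is a binary drug x feature matrix: cell (d, f) = 1 iff
drug d belongs to the support of feature f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graph_core import CanonicalGraph
from .mining import FeatureTable

POS = "POS"
NEG = "NEG"
DROP = "DROP"


class AmbiguityError(Exception):
    """An entry matches several distinct canonical nodes."""


# Published class sizes of the source classifications, used for sanity
# arithmetic and to document the default class maps.
DILIRANK_CLASS_SIZES = {
    "Most DILI concern": 192,
    "Ambiguous DILI concern": 254,
    "Less DILI concern": 278,
    "No DILI concern": 312,
}
DILIRANK_PRINTED_TOTAL = 1036

REGISCAR_CLASS_SIZES = {
    "Very probable": 18,
    "Probable": 19,
    "Possible": 94,
    "Unlikely": 697,
    "Very unlikely": 46,
}
REGISCAR_PRINTED_TOTAL = 874

# Sub-sample sizes after mapping/SMILES eligibility, as published.
DILI_SUBSAMPLE_SIZES = {POS: 146, NEG: 224}
DILI_SUBSAMPLE_PRINTED_TOTAL = 370
SCAR_SUBSAMPLE_SIZES = {POS: 102, NEG: 290}
SCAR_SUBSAMPLE_PRINTED_TOTAL = 392

#: Default groupings: Most-concern vs No-concern for DILI (middle classes
#: dropped); probable/possible vs unlikely for SCAR.
DILI_CLASS_MAP = {
    "Most DILI concern": POS,
    "Ambiguous DILI concern": DROP,
    "Less DILI concern": DROP,
    "No DILI concern": NEG,
}
SCAR_CLASS_MAP = {
    "Very probable": POS,
    "Probable": POS,
    "Possible": POS,
    "Unlikely": NEG,
    "Very unlikely": NEG,
}


@dataclass
class LabeledDrugSet:
    """POS/NEG assignments over canonical drug IRIs, with provenance."""

    assignments: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def positives(self) -> list[str]:
        return sorted(d for d, lab in self.assignments.items() if lab == POS)

    def negatives(self) -> list[str]:
        return sorted(d for d, lab in self.assignments.items() if lab == NEG)

    def drugs(self) -> list[str]:
        return sorted(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class MappingOptions:
    """How raw classification rows become POS/NEG labels.

    class_map sends each source class to POS, NEG, or DROP;
    require_smiles enforces the structure-description eligibility rule.
    """

    class_map: Mapping[str, str]
    require_smiles: bool = True


def _normalize_name(name: str) -> str:
    return " ".join(name.strip().lower().split())


@dataclass
class DrugAttributes:
    """External attribute table: per-IRI external ids, SMILES, synonyms."""

    external_id: dict[str, str] = field(default_factory=dict)  # iri -> id
    smiles: dict[str, str] = field(default_factory=dict)  # iri -> SMILES or ""
    synonyms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def read_tsv(cls, path: str) -> "DrugAttributes":
        attrs = cls()
        with open(path, encoding="utf-8") as handle:
            header = handle.readline().rstrip("\n").split("\t")
            cols = {name: i for i, name in enumerate(header)}
            for line in handle:
                row = line.rstrip("\n").split("\t")
                iri = row[cols["iri"]]
                attrs.external_id[iri] = row[cols["external_id"]]
                attrs.smiles[iri] = row[cols["smiles"]]
                syn = row[cols["synonyms"]]
                attrs.synonyms[iri] = tuple(s for s in syn.split("|") if s)
        return attrs

    def write_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("iri\texternal_id\tsmiles\tsynonyms\n")
            for iri in sorted(set(self.external_id) | set(self.smiles) | set(self.synonyms)):
                handle.write(
                    f"{iri}\t{self.external_id.get(iri, '')}\t"
                    f"{self.smiles.get(iri, '')}\t{'|'.join(self.synonyms.get(iri, ()))}\n"
                )


def map_expert_classification(
    entries: Sequence[Mapping[str, str]],
    cg: CanonicalGraph,
    attributes: DrugAttributes,
    options: MappingOptions,
) -> tuple[LabeledDrugSet, list[tuple[Mapping[str, str], str]]]:
    """Map raw classification rows onto canonical drugs.

    Each entry is a mapping with a ``source_class`` and either an ``id``
    (matched against the attribute table's external ids) or a ``name``
    (matched case-insensitively, whitespace-trimmed, against synonym
    lists and graph labels; no fuzzy matching).  An entry is included iff
    it matches exactly one canonical node and, when required, that node
    has a SMILES description.  Returns the labeled set plus a report of
    (entry, reason) for every excluded row.
    """
    id_index: dict[str, set[str]] = {}
    for iri, ext in attributes.external_id.items():
        if ext:
            id_index.setdefault(ext, set()).add(cg.rep(iri))
    name_index: dict[str, set[str]] = {}
    for iri, syns in attributes.synonyms.items():
        for syn in syns:
            name_index.setdefault(_normalize_name(syn), set()).add(cg.rep(iri))
    for iri, labels in cg.graph.labels.items():
        for lab in labels:
            name_index.setdefault(_normalize_name(lab), set()).add(iri)

    smiles_of: dict[str, str] = {}
    for iri, smi in attributes.smiles.items():
        rep = cg.rep(iri)
        if smi:
            smiles_of[rep] = smi

    labeled = LabeledDrugSet()
    report: list[tuple[Mapping[str, str], str]] = []
    for entry in entries:
        source_class = entry["source_class"]
        label = options.class_map.get(source_class)
        if label is None:
            report.append((entry, f"unknown source class {source_class!r}"))
            continue
        if label == DROP:
            report.append((entry, f"source class {source_class!r} dropped by options"))
            continue
        candidates: set[str] = set()
        if entry.get("id"):
            candidates = id_index.get(entry["id"], set())
        elif entry.get("name"):
            candidates = name_index.get(_normalize_name(entry["name"]), set())
        if not candidates:
            report.append((entry, "no match to a canonical node"))
            continue
        if len(candidates) > 1:
            raise AmbiguityError(
                f"entry {entry!r} matches several canonical nodes: {sorted(candidates)}"
            )
        (iri,) = candidates
        if options.require_smiles and iri not in smiles_of:
            report.append((entry, "no SMILES description"))
            continue
        labeled.assignments[iri] = label
        labeled.provenance[iri] = source_class
    return labeled, report


@dataclass
class BinaryMatrix:
    """Dense binary drug x feature matrix with deterministic ordering."""

    drugs: tuple[str, ...]
    feature_ids: tuple[str, ...]
    data: np.ndarray  # shape (n_drugs, n_features), dtype uint8

    def column_sums(self) -> np.ndarray:
        return self.data.sum(axis=0)

    def labels_vector(self, labeled: LabeledDrugSet) -> np.ndarray:
        return np.array([labeled.assignments[d] == POS for d in self.drugs], dtype=bool)

    def write_dense_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("drug_iri\t" + "\t".join(self.feature_ids) + "\n")
            for i, drug in enumerate(self.drugs):
                handle.write(drug + "\t" + "\t".join(map(str, self.data[i])) + "\n")

    def write_sparse_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("drug_iri\tfeature_id\n")
            rows, cols = np.nonzero(self.data)
            for i, j in zip(rows, cols):
                handle.write(f"{self.drugs[i]}\t{self.feature_ids[j]}\n")


def to_binary_matrix(table: FeatureTable, drugs: LabeledDrugSet | Iterable[str]) -> BinaryMatrix:
    """Binary membership matrix: cell (d, f) = 1 iff d in support(f).

    Rows and columns are sorted, so the matrix is a deterministic
    function of its inputs.
    """
    if isinstance(drugs, LabeledDrugSet):
        drug_list = tuple(drugs.drugs())
    else:
        drug_list = tuple(sorted(set(drugs)))
    supports = table.supports()
    feature_ids = tuple(sorted(supports))
    data = np.zeros((len(drug_list), len(feature_ids)), dtype=np.uint8)
    drug_pos = {d: i for i, d in enumerate(drug_list)}
    for j, fid in enumerate(feature_ids):
        for d in supports[fid]:
            i = drug_pos.get(d)
            if i is not None:
                data[i, j] = 1
    return BinaryMatrix(drugs=drug_list, feature_ids=feature_ids, data=data)
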