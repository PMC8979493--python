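"""Binary feature-matrix construction from annotated mutations and metadata.

Mutations annotated against a curated cancer-gene knowledge base are
grouped per gene into Activating / Inactivating / Other features labelled
``GENE(A)``, ``GENE(I)``, ``GENE(O)``; sample metadata contributes one
mutually exclusive binary row per cancer type, labelled
``CancerType:<name>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from ._util import logger

__all__ = [
    "MutationRecord",
    "FeatureMatrix",
    "VocabularyError",
    "group_mutation_features",
    "cancer_type_features",
    "merge_feature_matrices",
    "parse_feature_label",
]

ONCOGENIC_VOCAB = {
    "Oncogenic",
    "Likely Oncogenic",
    "Likely Neutral",
    "Inconclusive",
    "Unknown",
    "Resistance",
}
_ONCOGENIC_POSITIVE = {"Oncogenic", "Likely Oncogenic"}
_EFFECT_GAIN = {"Gain-of-function", "Likely Gain-of-function"}
_EFFECT_LOSS = {"Loss-of-function", "Likely Loss-of-function"}

NON_CODING_CLASSES = {"silent", "other conserving", "other_conserving"}

_LABEL_RE = re.compile(r"^(?P<gene>.+)\((?P<cls>[AIO])\)$")


class VocabularyError(ValueError):
    """Unknown controlled-vocabulary value in an annotation column."""


@dataclass
class MutationRecord:
    gene: str
    sample: str
    variant_class: str
    protein_change: str = ""
    in_oncokb: bool = False
    oncogenic: str = "Unknown"
    mutation_effect: str = "Unknown"

    def __post_init__(self):
        if not self.gene or not self.sample:
            raise ValueError("gene and sample must be non-empty")


@dataclass
class FeatureMatrix:
    """Binary m x n feature matrix with per-row kind annotations."""

    feature_ids: list
    sample_ids: list
    a: np.ndarray
    feature_kind: list = field(default_factory=list)  # "mutation" | "cancer_type"

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.int8)
        if self.a.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if not self.feature_kind:
            self.feature_kind = ["mutation"] * len(self.feature_ids)
        if len(self.feature_kind) != len(self.feature_ids):
            raise ValueError("feature_kind length mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def m(self) -> int:
        return len(self.feature_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def row(self, feature_id) -> np.ndarray:
        return self.a[self.feature_ids.index(feature_id)]


def parse_feature_label(label: str) -> tuple[str, str] | None:
    """Split ``GENE(A|I|O)`` into (gene, class); None for other labels."""
    m = _LABEL_RE.match(label)
    return (m.group("gene"), m.group("cls")) if m else None


def classify_mutation(oncogenic: str, mutation_effect: str) -> str:
    """Map annotation categories to a feature class A, I, or O.

    Rules: non-oncogenic (incl. Resistance) -> O; oncogenic with (likely)
    gain-of-function -> A; with (likely) loss-of-function -> I; oncogenic
    with any other effect -> O.
    """
    if oncogenic not in ONCOGENIC_VOCAB:
        raise VocabularyError(f"unknown ONCOGENIC value {oncogenic!r}")
    if oncogenic == "Resistance":
        logger.warning("classify_mutation: ONCOGENIC='Resistance' mapped to class O")
    if oncogenic not in _ONCOGENIC_POSITIVE:
        return "O"
    if mutation_effect in _EFFECT_GAIN:
        return "A"
    if mutation_effect in _EFFECT_LOSS:
        return "I"
    return "O"


def group_mutation_features(
    records: Iterable[MutationRecord],
    sample_ids: list | None = None,
    min_freq: int = 1,
) -> FeatureMatrix:
    """Build the mutation-feature rows of the binary matrix.

    Silent / other-conserving records and genes absent from the knowledge
    base are dropped. ``a[i, j] = 1`` iff sample j carries at least one
    mutation mapped to feature i. All-zero (or sub-``min_freq``) features
    are dropped.
    """
    records = list(records)
    bad = []
    for idx, rec in enumerate(records):
        if rec.oncogenic not in ONCOGENIC_VOCAB:
            bad.append((idx, rec.gene, rec.sample, rec.oncogenic))
    if bad:
        raise VocabularyError(f"unknown ONCOGENIC values in rows: {bad[:10]}")

    usable = [
        r
        for r in records
        if r.in_oncokb and r.variant_class.strip().lower() not in NON_CODING_CLASSES
    ]
    if sample_ids is None:
        sample_ids = sorted({r.sample for r in usable})
    sample_index = {s: j for j, s in enumerate(sample_ids)}

    cells: dict[str, set] = {}
    for r in usable:
        if r.sample not in sample_index:
            continue
        label = f"{r.gene}({classify_mutation(r.oncogenic, r.mutation_effect)})"
        cells.setdefault(label, set()).add(sample_index[r.sample])

    labels = sorted(lab for lab, js in cells.items() if len(js) >= max(1, min_freq))
    a = np.zeros((len(labels), len(sample_ids)), dtype=np.int8)
    for i, lab in enumerate(labels):
        a[i, sorted(cells[lab])] = 1
    return FeatureMatrix(labels, list(sample_ids), a, ["mutation"] * len(labels))


def cancer_type_features(metadata: Mapping[str, str], sample_ids: list | None = None) -> FeatureMatrix:
    """One binary row per distinct cancer-type label; rows are disjoint."""
    if sample_ids is None:
        sample_ids = sorted(metadata)
    missing = [s for s in sample_ids if not str(metadata.get(s, "") or "").strip()]
    if missing:
        raise ValueError(f"samples missing a cancer-type label: {missing}")
    types = sorted({str(metadata[s]).strip() for s in sample_ids})
    a = np.zeros((len(types), len(sample_ids)), dtype=np.int8)
    tindex = {t: i for i, t in enumerate(types)}
    for j, s in enumerate(sample_ids):
        a[tindex[str(metadata[s]).strip()], j] = 1
    labels = [f"CancerType:{t}" for t in types]
    return FeatureMatrix(labels, list(sample_ids), a, ["cancer_type"] * len(types))


def merge_feature_matrices(mut: FeatureMatrix, ct: FeatureMatrix) -> FeatureMatrix:
    """Row-wise concatenation after aligning the second matrix's samples by id."""
    if set(mut.sample_ids) != set(ct.sample_ids):
        only_a = set(mut.sample_ids) - set(ct.sample_ids)
        only_b = set(ct.sample_ids) - set(mut.sample_ids)
        raise ValueError(f"sample-id mismatch: only-left={sorted(only_a)[:5]} only-right={sorted(only_b)[:5]}")
    order = [ct.sample_ids.index(s) for s in mut.sample_ids]
    return FeatureMatrix(
        mut.feature_ids + ct.feature_ids,
        list(mut.sample_ids),
        np.vstack([mut.a.reshape(mut.m, mut.n), ct.a[:, order].reshape(ct.m, mut.n)]),
        list(mut.feature_kind) + list(ct.feature_kind),
    )
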