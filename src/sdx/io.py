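"""Readers and writers for the external file surfaces.

All tabular formats are plain text: comma-separated for matrices,
tab-separated for tables, UTF-8, '.' decimal. Writers are atomic
(temp file + rename) and stamp a ``#`` manifest comment line that the
readers skip.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import logger
from .features import FeatureMatrix, MutationRecord
from .scoring import DependencyMatrix

__all__ = [
    "read_dependency_matrix",
    "write_dependency_matrix",
    "read_mutation_table",
    "write_mutation_table",
    "read_metadata",
    "write_metadata",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_associations",
    "read_associations",
    "atomic_write_text",
]

_ENTREZ_RE = re.compile(r"^(?P<symbol>.*\S)\s*\((?P<entrez>\d+)\)$")

MUTATION_GENE_COL = "Hugo_Symbol"
MUTATION_SAMPLE_COLS = ("Tumor_Sample_Barcode", "DepMap_ID")
MUTATION_CLASS_COL = "Variant_Classification"
MUTATION_PROTEIN_COL = "Protein_Change"
ANNOT_COLS = ("GENE_IN_ONCOKB", "ONCOGENIC", "MUTATION_EFFECT")


def atomic_write_text(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".sdx-tmp-")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def manifest_line(seed=None, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"# sdx={__version__}"]
    if config_hash:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def split_entrez(label: str) -> tuple[str, int | None]:
    """'BRAF (673)' -> ('BRAF', 673); plain symbols pass through."""
    m = _ENTREZ_RE.match(str(label).strip())
    if m:
        return m.group("symbol"), int(m.group("entrez"))
    return str(label).strip(), None


def read_dependency_matrix(path: str, genes_in: str = "rows") -> DependencyMatrix:
    """Read a dependency-score CSV; ids in the first column.

    ``genes_in`` selects orientation ("rows" or "cols"). Gene symbols may
    carry a trailing " (EntrezID)" suffix, which is stripped. Missing
    cells become NaN; non-numeric body cells raise with coordinates.
    """
    df = pd.read_csv(path, index_col=0, comment="#")
    if genes_in == "cols":
        df = df.T
    elif genes_in != "rows":
        raise ValueError("genes_in must be 'rows' or 'cols'")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna() & (df.astype(str).apply(lambda s: s.str.strip()) != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    gene_ids = [split_entrez(g)[0] for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids after suffix stripping: {dupes[:5]}")
    return DependencyMatrix(gene_ids, [str(c) for c in df.columns], body.to_numpy(dtype=float))


def write_dependency_matrix(matrix: DependencyMatrix, path: str, seed=None) -> None:
    df = pd.DataFrame(matrix.scores, index=matrix.gene_ids, columns=matrix.sample_ids)
    atomic_write_text(path, manifest_line(seed) + df.to_csv())


def read_mutation_table(path: str) -> list[MutationRecord]:
    """Read a MAF-like mutation table with oncokb-annotator columns.

    Accepts tab or comma delimiting (sniffed). Silent / other-conserving
    rows are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in (MUTATION_GENE_COL, MUTATION_CLASS_COL, *ANNOT_COLS) if c not in df.columns]
    sample_col = next((c for c in MUTATION_SAMPLE_COLS if c in df.columns), None)
    if sample_col is None:
        missing.append(" or ".join(MUTATION_SAMPLE_COLS))
    if missing:
        raise ValueError(f"mutation table missing required columns: {missing}")

    from .features import NON_CODING_CLASSES

    cls = df[MUTATION_CLASS_COL].astype(str).str.strip().str.lower()
    n_dropped = int(cls.isin(NON_CODING_CLASSES).sum())
    if n_dropped:
        logger.warning("read_mutation_table: dropped %d silent/other-conserving rows", n_dropped)
    df = df[~cls.isin(NON_CODING_CLASSES)]

    def as_bool(v) -> bool:
        return str(v).strip().lower() in {"true", "1", "yes"}

    records = []
    for row in df.itertuples(index=False):
        rd = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        records.append(
            MutationRecord(
                gene=str(rd[MUTATION_GENE_COL]),
                sample=str(rd[sample_col]),
                variant_class=str(rd[MUTATION_CLASS_COL]),
                protein_change=str(rd.get(MUTATION_PROTEIN_COL, "") or ""),
                in_oncokb=as_bool(rd["GENE_IN_ONCOKB"]),
                oncogenic=str(rd["ONCOGENIC"]),
                mutation_effect=str(rd["MUTATION_EFFECT"]),
            )
        )
    return records


def write_mutation_table(records: list[MutationRecord], path: str) -> None:
    df = pd.DataFrame(
        {
            MUTATION_GENE_COL: [r.gene for r in records],
            "DepMap_ID": [r.sample for r in records],
            MUTATION_CLASS_COL: [r.variant_class for r in records],
            MUTATION_PROTEIN_COL: [r.protein_change for r in records],
            "GENE_IN_ONCOKB": [r.in_oncokb for r in records],
            "ONCOGENIC": [r.oncogenic for r in records],
            "MUTATION_EFFECT": [r.mutation_effect for r in records],
        }
    )
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_metadata(path: str, type_column: str = "Cancer_type") -> dict:
    df = pd.read_csv(path, comment="#")
    if type_column not in df.columns:
        raise ValueError(f"metadata missing column {type_column!r}; has {list(df.columns)}")
    id_col = df.columns[0]
    mapping = {}
    unlabeled = []
    for sid, label in zip(df[id_col], df[type_column]):
        label = "" if pd.isna(label) else str(label).strip()
        if not label:
            unlabeled.append(str(sid))
        mapping[str(sid)] = label
    if unlabeled:
        raise ValueError(f"samples with missing cancer-type label: {unlabeled}")
    return mapping


def write_metadata(metadata: Mapping[str, str], path: str, type_column: str = "Cancer_type") -> None:
    df = pd.DataFrame({"DepMap_ID": list(metadata), type_column: list(metadata.values())})
    atomic_write_text(path, df.to_csv(index=False))


def write_feature_matrix(fm: FeatureMatrix, path: str, dense: bool = False, seed=None) -> None:
    """Sparse triplet TSV (feature, sample, kind) by default; dense CSV optionally."""
    if dense:
        df = pd.DataFrame(fm.a, index=fm.feature_ids, columns=fm.sample_ids)
        atomic_write_text(path, manifest_line(seed) + df.to_csv())
        return
    lines = [manifest_line(seed), "feature\tsample\tkind\n"]
    for i, (lab, kind) in enumerate(zip(fm.feature_ids, fm.feature_kind)):
        for j in np.flatnonzero(fm.a[i]):
            lines.append(f"{lab}\t{fm.sample_ids[j]}\t{kind}\n")
    atomic_write_text(path, "".join(lines))


def read_feature_matrix(path: str, dense: bool = False, sample_ids: list | None = None) -> FeatureMatrix:
    if dense:
        df = pd.read_csv(path, index_col=0, comment="#")
        return FeatureMatrix(
            [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=np.int8)
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    feats: list[str] = []
    kinds: dict[str, str] = {}
    for lab, kind in zip(df["feature"], df["kind"]):
        if lab not in kinds:
            feats.append(str(lab))
            kinds[str(lab)] = str(kind)
    if sample_ids is None:
        sample_ids = sorted({str(s) for s in df["sample"]})
    a = np.zeros((len(feats), len(sample_ids)), dtype=np.int8)
    fidx = {f: i for i, f in enumerate(feats)}
    sidx = {s: j for j, s in enumerate(sample_ids)}
    for lab, s in zip(df["feature"], df["sample"]):
        a[fidx[str(lab)], sidx[str(s)]] = 1
    return FeatureMatrix(feats, list(sample_ids), a, [kinds[f] for f in feats])


ASSOC_COLUMNS = [
    "profile",
    "direction",
    "features",
    "weight",
    "p_features",
    "p_set",
    "q",
    "n_perm",
    "covered_responsive",
    "total_responsive",
]


def write_associations(rows: list[dict], path: str, seed=None, config_hash=None) -> None:
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    atomic_write_text(
        path, manifest_line(seed, config_hash) + df.to_csv(sep="\t", index=False)
    )


def read_associations(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj, path: str) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
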