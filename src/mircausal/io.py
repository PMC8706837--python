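"""Readers and writers for the pipeline's tab-separated interfaces.

All inputs are plain text: a causal association table (HMDD-style), miRNA
FASTA files (precursor / mature / seed), miRNA x cell-type expression and
miRNA x pathway p-value tables, and a disease -> MeSH-tree-number mapping.
Predictions and matrices are written back as tab-separated tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import (
    LABELS,
    AssociationMatrix,
    ConfigurationError,
    InputError,
    ScoreMatrix,
    ShapeError,
    SimilarityMatrix,
    normalize_mirna_id,
    strip_arm_suffix,
)

log = logging.getLogger(__name__)

#: spellings of the causal flag accepted out of the box
DEFAULT_LABEL_MAP = {
    "causal": "causal",
    "yes": "causal",
    "1": "causal",
    "true": "causal",
    "non-causal": "non-causal",
    "noncausal": "non-causal",
    "no": "non-causal",
    "0": "non-causal",
    "false": "non-causal",
    "none": "none",
    "unknown": "none",
    "na": "none",
}

#: deduplication precedence: strongest evidence wins
_LABEL_RANK = {"causal": 0, "non-causal": 1, "none": 2}


@dataclass
class TableDialect:
    """Column names and label vocabulary of an association table."""

    mirna_col: str = "mirna"
    disease_col: str = "disease"
    label_col: str = "causality"
    label_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))


def load_association_table(path: str | Path, dialect: TableDialect | None = None) -> pd.DataFrame:
    """Load a three-level (causal / non-causal / none) association table.

    Duplicate (miRNA, disease) pairs are collapsed keeping the strongest
    label (causal > non-causal > none).  Returns a DataFrame with columns
    ``mirna``, ``disease``, ``label``.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise InputError(f"association table {path} has no rows")
    for col in (dialect.mirna_col, dialect.disease_col, dialect.label_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"association table {path} is missing column {col!r} "
                f"(found: {list(df.columns)})"
            )
    out = pd.DataFrame(
        {
            "mirna": df[dialect.mirna_col].map(normalize_mirna_id),
            "disease": df[dialect.disease_col].str.strip(),
            "label": df[dialect.label_col].str.strip().str.lower(),
        }
    )
    unknown = set(out["label"]) - set(dialect.label_map)
    if unknown:
        raise ConfigurationError(
            f"unrecognized causal labels {sorted(unknown)}; extend the dialect label_map"
        )
    out["label"] = out["label"].map(dialect.label_map)
    out["_rank"] = out["label"].map(_LABEL_RANK)
    out = (
        out.sort_values("_rank", kind="stable")
        .drop_duplicates(subset=["mirna", "disease"], keep="first")
        .drop(columns="_rank")
    )
    # restore first-appearance order of the input file
    out = out.sort_index().reset_index(drop=True)
    return out


def build_association_matrix(
    table: pd.DataFrame, label_filter: Iterable[str] = ("causal",)
) -> AssociationMatrix:
    """Build the binary nm x nd matrix MD from a three-level table.

    Rows/columns are ordered by first appearance in the table; an entry is 1
    iff the pair's label is in ``label_filter`` (default: causal only).
    """
    if table.empty:
        raise InputError("cannot build an association matrix from an empty table")
    label_filter = set(label_filter)
    bad = label_filter - set(LABELS)
    if bad:
        raise ConfigurationError(f"unknown labels in filter: {sorted(bad)}")
    mirna_ids = tuple(dict.fromkeys(table["mirna"]))
    disease_ids = tuple(dict.fromkeys(table["disease"]))
    mi = {x: i for i, x in enumerate(mirna_ids)}
    di = {x: i for i, x in enumerate(disease_ids)}
    values = np.zeros((len(mirna_ids), len(disease_ids)))
    for row in table.itertuples(index=False):
        if row.label in label_filter:
            values[mi[row.mirna], di[row.disease]] = 1.0
    return AssociationMatrix(values, mirna_ids, disease_ids)


def label_grid(table: pd.DataFrame, md: AssociationMatrix) -> np.ndarray:
    """nm x nd array of labels ('causal'/'non-causal'/'none') on MD's grid.

    Cells absent from the table are 'none'.
    """
    grid = np.full(md.shape, "none", dtype=object)
    for row in table.itertuples(index=False):
        i = md.mirna_index.get(row.mirna)
        j = md.disease_index.get(row.disease)
        if i is not None and j is not None:
            grid[i, j] = row.label
    return grid


def load_mirna_fasta(path: str | Path) -> dict[str, str]:
    """Read a miRNA FASTA file into an id -> sequence map.

    Ids are lowercased; sequences are uppercased with T transliterated to U.
    """
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    seqs[current] = "".join(chunks)
                current = normalize_mirna_id(line[1:].split()[0])
                chunks = []
            else:
                if current is None:
                    raise InputError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                chunks.append(line.upper().replace("T", "U"))
    if current is not None:
        seqs[current] = "".join(chunks)
    return seqs


def collapse_mature_arms(seqs: Mapping[str, str]) -> dict[str, str]:
    """Map mature-arm ids (hsa-mir-21-5p) onto precursor-level ids.

    When both arms are present the first-listed one is kept, so the result
    is deterministic in file order.
    """
    out: dict[str, str] = {}
    for name, seq in seqs.items():
        key = strip_arm_suffix(name)
        out.setdefault(key, seq)
    return out


def _load_numeric_table(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_mirna_id(str(x)) for x in df.index]
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise InputError(
                f"{kind} table {path}: non-numeric value in column {col!r}, row {row!r}"
            ) from exc
    return df


def load_expression_table(path: str | Path) -> pd.DataFrame:
    """miRNA x cell-type real-valued expression table (NaN = missing)."""
    return _load_numeric_table(path, "expression")


def load_pathway_table(path: str | Path) -> pd.DataFrame:
    """miRNA x pathway enrichment p-value table (NaN = missing)."""
    return _load_numeric_table(path, "pathway p-value")


def load_mesh_mapping(path: str | Path) -> dict[str, list[str]]:
    """Disease -> MeSH tree numbers, one row per disease, codes ';'-separated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"MeSH mapping {path} needs at least two columns")
    mapping: dict[str, list[str]] = {}
    for name_raw, codes_raw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        name = str(name_raw).strip()
        codes = [c.strip() for c in str(codes_raw).split(";") if c.strip()]
        mapping.setdefault(name, []).extend(codes)
    return mapping


def write_predictions(
    scores: ScoreMatrix,
    known: AssociationMatrix,
    path: str | Path,
    sort_mode: str = "disease",
) -> pd.DataFrame:
    """Write a ranked prediction table (rank, mirna, disease, score, known_causal).

    ``sort_mode`` groups the ranking per miRNA, per disease, or over all
    cells ('any').  Ties break deterministically by (score desc, mirna asc,
    disease asc).
    """
    if sort_mode not in ("mirna", "disease", "any"):
        raise ConfigurationError(f"unknown sort_mode {sort_mode!r}")
    if not scores.aligned_with(known):
        raise ShapeError("score and association matrices have different indices")
    nm, nd = scores.values.shape
    df = pd.DataFrame(
        {
            "mirna": np.repeat(scores.mirna_ids, nd),
            "disease": np.tile(scores.disease_ids, nm),
            "score": scores.values.ravel(),
            "known_causal": known.values.ravel().astype(int),
        }
    )
    df["_neg"] = -df["score"]
    if sort_mode == "any":
        df = df.sort_values(["_neg", "mirna", "disease"], kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        group = sort_mode
        df = df.sort_values([group, "_neg", "mirna", "disease"], kind="stable")
        df["rank"] = df.groupby(group, sort=False).cumcount() + 1
    df = df.drop(columns="_neg")[["rank", "mirna", "disease", "score", "known_causal"]]
    df.to_csv(path, sep="\t", index=False)
    return df.reset_index(drop=True)


def write_matrix(matrix: SimilarityMatrix | ScoreMatrix | AssociationMatrix, path: str | Path) -> None:
    """Export any labelled matrix as tab-separated with row/column ids."""
    if isinstance(matrix, SimilarityMatrix):
        frame = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    else:
        frame = pd.DataFrame(
            matrix.values, index=matrix.mirna_ids, columns=matrix.disease_ids
        )
    frame.to_csv(path, sep="\t")


def read_similarity_matrix(path: str | Path, bounds=(0.0, 1.0)) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(df.to_numpy(dtype=float), tuple(str(c) for c in df.columns), bounds)


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        df.to_numpy(dtype=float),
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
    )
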