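"""Core domain containers shared across the pipeline.

The pipeline operates on three kinds of matrices: a binary miRNA x disease
association matrix, square symmetric similarity matrices (one per evidence
source), and real-valued prediction score matrices.  All carry ordered
id indices so that rows/columns are aligned by name, not by position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

LABELS = ("causal", "non-causal", "none")

#: alphabet of RNA sequences after io normalization
RNA_ALPHABET = frozenset("ACGU")


class ShapeError(ValueError):
    """Indices or shapes of two matrices do not line up."""


class ConfigurationError(ValueError):
    """Invalid configuration (weights, columns, thresholds)."""


class InputError(ValueError):
    """Malformed or empty input file."""


def _build_index(ids: Sequence[str]) -> dict[str, int]:
    index = {x: i for i, x in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate ids in index")
    return index


@dataclass
class MirnaRecord:
    """Feature bundle for one miRNA (precursor-level id)."""

    id: str
    seed_seq: str = ""
    mature_seq: str = ""
    precursor_seq: str = ""
    expression_string: str = ""
    pathway_string: str = ""


@dataclass
class DiseaseRecord:
    """A disease term with its MeSH tree numbers (dot-delimited codes)."""

    id: str
    tree_numbers: tuple[str, ...] = ()


@dataclass
class AssociationMatrix:
    """Binary nm x nd matrix MD with MD[i, j] = 1 iff miRNA i is causally
    associated with disease j (or, more generally, the pair's label falls in
    the filter used to build the matrix)."""

    values: np.ndarray
    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    mirna_index: dict[str, int] = field(init=False, repr=False)
    disease_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ShapeError(
                f"association matrix shape {self.values.shape} != "
                f"({len(self.mirna_ids)}, {len(self.disease_ids)})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.mirna_index = _build_index(self.mirna_ids)
        self.disease_index = _build_index(self.disease_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def positives(self) -> list[tuple[str, str]]:
        """(mirna_id, disease_id) pairs of all 1-cells, row-major order."""
        rows, cols = np.nonzero(self.values)
        return [(self.mirna_ids[i], self.disease_ids[j]) for i, j in zip(rows, cols)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), self.mirna_ids, self.disease_ids)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with unit diagonal.

    ``bounds`` declares the admissible value range (e.g. (0, 1) for a
    Gaussian kernel, (-inf, 1) is never used here).
    """

    values: np.ndarray
    ids: tuple[str, ...]
    bounds: tuple[float, float] = (0.0, 1.0)
    index: dict[str, int] = field(init=False, repr=False)

    SYMMETRY_TOL = 1e-12

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ShapeError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if n and np.abs(self.values - self.values.T).max() > self.SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if n and np.abs(np.diag(self.values) - 1.0).max() > self.SYMMETRY_TOL:
            raise ValueError("similarity matrix diagonal must be 1")
        lo, hi = self.bounds
        if n and ((self.values < lo - 1e-9).any() or (self.values > hi + 1e-9).any()):
            raise ValueError(f"similarity values outside declared bounds {self.bounds}")
        self.index = _build_index(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores over the same grid as an AssociationMatrix."""

    values: np.ndarray
    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ShapeError("score matrix shape does not match its indices")

    def aligned_with(self, other: "AssociationMatrix | ScoreMatrix") -> bool:
        return (
            self.mirna_ids == tuple(other.mirna_ids)
            and self.disease_ids == tuple(other.disease_ids)
        )


@dataclass
class ModelConfig:
    """Hyperparameters of the full pipeline.

    k, lambda1/lambda2, max_iters, tol and seed drive the factorization;
    seq_weights combine the precursor/mature/seed similarity matrices into
    the sequence source; integration_weights combine the four per-source
    score matrices; delta is the semantic decay factor of the disease DAG
    similarity.
    """

    k: int = 64
    lambda1: float = 1.0
    lambda2: float = 1.0
    max_iters: int = 500
    tol: float = 1e-6
    seed: int = 0
    seq_weights: tuple[float, float, float] = (0.05, 0.05, 0.9)
    integration_weights: tuple[float, float, float, float] = (0.35, 0.4, 0.15, 0.1)
    delta: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.seq_weights) - 1.0) > 1e-9:
            raise ConfigurationError("seq_weights must sum to 1")
        if abs(sum(self.integration_weights) - 1.0) > 1e-9:
            raise ConfigurationError("integration_weights must sum to 1")
        if not 0.0 < self.delta < 1.0:
            raise ConfigurationError("delta must lie in (0, 1)")
        if self.k < 1:
            raise ConfigurationError("k must be positive")

    @classmethod
    def from_json(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("seq_weights", "integration_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "max_iters": self.max_iters,
            "tol": self.tol,
            "seed": self.seed,
            "seq_weights": list(self.seq_weights),
            "integration_weights": list(self.integration_weights),
            "delta": self.delta,
        }


def normalize_mirna_id(name: str) -> str:
    """Lowercase a miRNA name ('hsa-miR-21' -> 'hsa-mir-21')."""
    return name.strip().lower()


def strip_arm_suffix(name: str) -> str:
    """Drop a trailing -5p/-3p arm suffix to reach precursor granularity."""
    lowered = normalize_mirna_id(name)
    for suffix in ("-5p", "-3p"):
        if lowered.endswith(suffix):
            return lowered[: -len(suffix)]
    return lowered
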