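"""Edit-distance similarity between miRNA feature strings.

Any miRNA feature that can be written as a string over a fixed alphabet
(precursor / mature / seed sequence, discretized expression profile,
discretized pathway-enrichment profile) is compared by Levenshtein
distance LD and turned into a similarity

    MS(m1, m2) = 1 - LD(m1, m2) / (len(m1) + len(m2)),

which is 1 for identical strings and, for equal-length strings, bounded
below by 0.5 (at most max(len) edits are ever needed).  Per-feature
matrices are combined by a convex weighted sum.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import edlib
import numpy as np

from .types import ConfigurationError, ShapeError, SimilarityMatrix


def levenshtein_distance(s1: str, s2: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if s1 == s2:
        return 0
    return edlib.align(s1, s2, task="distance")["editDistance"]


def pair_similarity(s1: str, s2: str) -> float:
    """Length-normalized edit similarity, 1 - LD/(len1+len2).

    Undefined when both strings are empty (zero denominator).
    """
    total = len(s1) + len(s2)
    if total == 0:
        raise ValueError("pair_similarity is undefined for two empty strings")
    return 1.0 - levenshtein_distance(s1, s2) / total


def similarity_matrix(strings: Mapping[str, str]) -> SimilarityMatrix:
    """All-pairs edit similarity over an id -> feature-string map.

    Ids mapped to an empty string (missing data) get similarity 0 to every
    other id and 1 to themselves, so no miRNA is silently dropped.
    """
    ids = tuple(strings)
    if not ids:
        raise ValueError("similarity_matrix needs at least one id")
    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        sa = strings[ids[a]]
        for b in range(a + 1, n):
            sb = strings[ids[b]]
            if not sa or not sb:
                continue  # missing feature: keep 0
            values[a, b] = values[b, a] = pair_similarity(sa, sb)
    return SimilarityMatrix(values, ids)


def combine_weighted(
    matrices: Sequence[SimilarityMatrix], weights: Sequence[float]
) -> SimilarityMatrix:
    """Convex combination of similarity matrices sharing one index."""
    if len(matrices) != len(weights):
        raise ConfigurationError("one weight per matrix required")
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigurationError("weights must be non-negative and sum to 1")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.ids != ref.ids:
            raise ShapeError("similarity matrices have mismatched indices")
    values = sum(w * m.values for w, m in zip(weights, matrices))
    return SimilarityMatrix(values, ref.ids)
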