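"""Weighted integration of the four per-source score matrices.

One factorization model is trained per miRNA similarity source — sequence
(S), expression (E), pathway (P) and GIP kernel (G) — and their score
matrices are combined by a convex weighted sum, by default
0.35*S + 0.4*E + 0.15*P + 0.1*G.  The weights can be re-fit by exhaustive
search over the simplex lattice with a given step (0.05 in the reference
setting), maximizing validation AUROC.
"""

from __future__ import annotations

from math import comb
from typing import Sequence

import numpy as np

from .evaluation import auroc
from .types import ConfigurationError, ScoreMatrix, ShapeError

DEFAULT_WEIGHTS = (0.35, 0.4, 0.15, 0.1)


def integrate_scores(
    scores: Sequence[ScoreMatrix], weights: Sequence[float] = DEFAULT_WEIGHTS
) -> ScoreMatrix:
    """Entrywise convex combination of aligned score matrices."""
    if len(scores) != len(weights):
        raise ConfigurationError("one weight per score matrix required")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ConfigurationError("integration weights must be non-negative and sum to 1")
    ref = scores[0]
    for s in scores[1:]:
        if not s.aligned_with(ref):
            raise ShapeError("score matrices have mismatched indices")
    values = sum(wi * s.values for wi, s in zip(w, scores))
    return ScoreMatrix(values, ref.mirna_ids, ref.disease_ids)


def weight_lattice(n_sources: int, step: float) -> list[tuple[float, ...]]:
    """All non-negative weight tuples on the step lattice summing to 1.

    The count is the composition number C(1/step + n_sources - 1,
    n_sources - 1).
    """
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ConfigurationError("step must divide 1 evenly")

    def _parts(remaining: int, slots: int):
        if slots == 1:
            yield (remaining,)
            return
        for first in range(remaining + 1):
            for rest in _parts(remaining - first, slots - 1):
                yield (first, *rest)

    return [tuple(p * step for p in parts) for parts in _parts(units, n_sources)]


def lattice_size(n_sources: int, step: float) -> int:
    """Closed-form lattice cardinality C(1/step + n-1, n-1)."""
    units = round(1.0 / step)
    return comb(units + n_sources - 1, n_sources - 1)


def grid_search_weights(
    scores: Sequence[ScoreMatrix],
    positive_cells: Sequence[tuple[int, int]],
    negative_cells: Sequence[tuple[int, int]],
    step: float = 0.05,
) -> tuple[tuple[float, ...], float]:
    """Exhaustive simplex-lattice search maximizing validation AUROC.

    Ties break toward the lexicographically smallest weight tuple, so the
    result is deterministic.
    """
    if not positive_cells or not negative_cells:
        raise ValueError("grid search needs at least one positive and one negative cell")
    pos_idx = tuple(np.array(x) for x in zip(*positive_cells))
    neg_idx = tuple(np.array(x) for x in zip(*negative_cells))
    per_source = [
        np.concatenate([s.values[pos_idx], s.values[neg_idx]]) for s in scores
    ]
    labels = np.concatenate(
        [np.ones(len(positive_cells)), np.zeros(len(negative_cells))]
    )
    best: tuple[float, ...] | None = None
    best_auc = -np.inf
    for weights in sorted(weight_lattice(len(scores), step)):
        combined = sum(w * v for w, v in zip(weights, per_source))
        auc = auroc(combined, labels)
        if auc > best_auc + 1e-12:
            best_auc = auc
            best = weights
    assert best is not None
    return best, float(best_auc)
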