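"""Evaluation harness: splits, masking, AUROC and rank-sum comparisons.

The protocol follows standard link-prediction practice: known causal cells
are partitioned into folds (or a single independent test split); in each
round the test positives are zeroed in the association matrix, every
quantity that depends on the association matrix (the GIP kernel and the
factorization itself) is recomputed from the masked copy only, and the
held-out positives are scored against the untouched cells.  Scores of the
three pair groups (causal, non-causal, unassociated) are compared by AUROC
and the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .types import AssociationMatrix, ScoreMatrix

Cell = tuple[int, int]


class SplitError(ValueError):
    """A requested split is impossible for the given positives."""


class EvaluationError(ValueError):
    """Degenerate labels (no positives or no negatives)."""


def split_independent(
    positives: Sequence[Cell], fraction: float, seed: int
) -> tuple[list[Cell], list[Cell]]:
    """Random train/test partition of positive cells; |test| = round(fraction*n)."""
    if not 0.0 < fraction < 1.0:
        raise SplitError("fraction must lie in (0, 1)")
    n = len(positives)
    if n < 2:
        raise SplitError("need at least 2 positives to split")
    n_test = int(round(fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test = [positives[i] for i in order[:n_test]]
    train = [positives[i] for i in order[n_test:]]
    return train, test


def split_folds(positives: Sequence[Cell], n_folds: int, seed: int) -> np.ndarray:
    """Balanced random fold assignment (fold sizes differ by at most 1)."""
    n = len(positives)
    if n_folds < 2:
        raise SplitError("need at least 2 folds")
    if n_folds > n:
        raise SplitError(f"cannot make {n_folds} folds from {n} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


def mask_positives(md: AssociationMatrix, test_cells: Sequence[Cell]) -> AssociationMatrix:
    """Copy of MD with the given positive cells zeroed (leakage guard)."""
    masked = md.copy()
    for i, j in test_cells:
        if masked.values[i, j] != 1.0:
            raise ValueError(f"cell ({i}, {j}) is not a positive; cannot mask it")
        masked.values[i, j] = 0.0
    return masked


def auroc(scores: Sequence[float], labels: Sequence[float]) -> float:
    """Area under the ROC curve == Mann-Whitney pair statistic (ties 0.5)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("AUROC needs both positive and negative labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both groups have at most 8 tie-free values,
    normal approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """One pairwise comparison between score groups."""

    group_a: str
    group_b: str
    statistic: float
    pvalue: float


@dataclass
class EvaluationReport:
    """Summary of a score matrix against three-level labels."""

    group_sizes: dict[str, int]
    group_means: dict[str, float]
    causal_vs_none_auroc: float | None = None
    causal_vs_noncausal_auroc: float | None = None
    rank_sum: list[GroupComparison] = field(default_factory=list)
    fold_aurocs: list[float] = field(default_factory=list)
    pooled_auroc: float | None = None
    macro_auroc: float | None = None

    def to_dict(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "group_means": self.group_means,
            "causal_vs_none_auroc": self.causal_vs_none_auroc,
            "causal_vs_noncausal_auroc": self.causal_vs_noncausal_auroc,
            "rank_sum": [
                {
                    "groups": [c.group_a, c.group_b],
                    "statistic": c.statistic,
                    "pvalue": c.pvalue,
                }
                for c in self.rank_sum
            ],
            "fold_aurocs": self.fold_aurocs,
            "pooled_auroc": self.pooled_auroc,
            "macro_auroc": self.macro_auroc,
        }


def evaluate_groups(scores: ScoreMatrix, labels: np.ndarray) -> EvaluationReport:
    """Compare a fixed score matrix across causal / non-causal / none groups.

    ``labels`` is an nm x nd object array over the three-level vocabulary
    (see io.label_grid).  No model is retrained here: the score matrix is
    consumed as-is.  Comparisons with an empty group are reported as absent.
    """
    if labels.shape != scores.values.shape:
        raise ValueError("label grid and score matrix shapes differ")
    groups = {
        name: scores.values[labels == name] for name in ("causal", "non-causal", "none")
    }
    report = EvaluationReport(
        group_sizes={k: int(v.size) for k, v in groups.items()},
        group_means={k: (float(v.mean()) if v.size else float("nan")) for k, v in groups.items()},
    )
    causal, noncausal, none = groups["causal"], groups["non-causal"], groups["none"]
    if causal.size and none.size:
        report.causal_vs_none_auroc = auroc(
            np.concatenate([causal, none]),
            np.concatenate([np.ones(causal.size), np.zeros(none.size)]),
        )
    if causal.size and noncausal.size:
        report.causal_vs_noncausal_auroc = auroc(
            np.concatenate([causal, noncausal]),
            np.concatenate([np.ones(causal.size), np.zeros(noncausal.size)]),
        )
    for name_a, name_b in (
        ("causal", "non-causal"),
        ("causal", "none"),
        ("non-causal", "none"),
    ):
        if groups[name_a].size and groups[name_b].size:
            u, p = rank_sum_test(groups[name_a], groups[name_b])
            report.rank_sum.append(GroupComparison(name_a, name_b, u, p))
    return report
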