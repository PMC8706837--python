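"""Discretization of expression and pathway-enrichment profiles.

Expression values are binned per cell type into quartiles labelled A-D
(A = lowest quartile across all miRNAs in that cell type).  Pathway
enrichment p-values are graded by significance: C for p < 1e-4,
B for 1e-4 <= p < 0.01, A for 0.01 <= p < 0.05 and N for non-significant
p >= 0.05; pathways supported by fewer than three significant miRNAs are
discarded beforehand.  The resulting fixed-length strings feed the
edit-distance similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ConfigurationError


class EncodingError(ValueError):
    """A column cannot be discretized (e.g. entirely missing)."""


@dataclass
class EncodingSpec:
    """Binning rules for expression and pathway profiles."""

    expression_levels: str = "ABCD"
    expression_quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    #: (threshold, grade) pairs scanned in order; p below the first matching
    #: threshold gets that grade, otherwise the non-significant grade
    pathway_grades: tuple[tuple[float, str], ...] = ((1e-4, "C"), (0.01, "B"), (0.05, "A"))
    nonsignificant_grade: str = "N"
    min_significant_mirnas: int = 3
    significance_cutoff: float = 0.05

    def __post_init__(self) -> None:
        q = self.expression_quantiles
        if len(q) + 1 != len(self.expression_levels):
            raise ConfigurationError("need one label per quantile bin")
        if any(not 0 < x < 1 for x in q) or any(a >= b for a, b in zip(q, q[1:])):
            raise ConfigurationError("quantile fractions must be strictly increasing in (0,1)")
        ts = [t for t, _ in self.pathway_grades]
        if any(a >= b for a, b in zip(ts, ts[1:])):
            raise ConfigurationError("pathway grade thresholds must be strictly increasing")


def discretize_expression(table: pd.DataFrame, spec: EncodingSpec | None = None) -> dict[str, str]:
    """Encode each miRNA's expression profile as a string over A-D.

    Quartile cuts are computed per cell type (column) across all miRNAs
    using linear-interpolation sample quantiles; a value exactly at a cut
    goes to the lower bin.  Missing values take the lowest label.
    """
    spec = spec or EncodingSpec()
    if table.empty:
        raise EncodingError("expression table has no rows or columns")
    labels = np.array(list(spec.expression_levels))
    codes = np.zeros(table.shape, dtype=int)
    for jc, col in enumerate(table.columns):
        vals = table[col].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size == 0:
            raise EncodingError(f"expression column {col!r} is entirely missing")
        cuts = np.quantile(finite, spec.expression_quantiles)
        idx = np.searchsorted(cuts, vals, side="left")
        idx[np.isnan(vals)] = 0  # absent ~ not expressed
        codes[:, jc] = idx
    strings = ["".join(labels[row]) for row in codes]
    return dict(zip((str(i) for i in table.index), strings))


def filter_pathways(table: pd.DataFrame, spec: EncodingSpec | None = None) -> pd.DataFrame:
    """Keep only pathways significant (p < cutoff) in >= min_significant_mirnas miRNAs."""
    spec = spec or EncodingSpec()
    if table.empty:
        return table.copy()
    counts = (table < spec.significance_cutoff).sum(axis=0)
    keep = counts[counts >= spec.min_significant_mirnas].index
    return table[[c for c in table.columns if c in set(keep)]]


def grade_pvalue(p: float, spec: EncodingSpec) -> str:
    if np.isnan(p):
        return spec.nonsignificant_grade
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, grade in spec.pathway_grades:
        if p < threshold:
            return grade
    return spec.nonsignificant_grade


def discretize_pathways(table: pd.DataFrame, spec: EncodingSpec | None = None) -> dict[str, str]:
    """Encode each miRNA's (filtered) pathway p-value profile over {A,B,C,N}."""
    spec = spec or EncodingSpec()
    if table.shape[1] == 0:
        return {str(i): "" for i in table.index}
    strings = {}
    for mirna, row in zip(table.index, table.to_numpy(dtype=float)):
        strings[str(mirna)] = "".join(grade_pvalue(p, spec) for p in row)
    return strings
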