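"""End-to-end orchestration: similarities -> per-source models -> integration.

This module wires the individual stages together on a fixed miRNA/disease
universe (taken from the association matrix):

1. feature-based miRNA similarities (sequence, expression, pathway) and the
   disease semantic similarity, all independent of the association labels;
2. the association-derived GIP kernel, recomputed per training mask;
3. one factorization model per miRNA similarity source, sharing the disease
   semantic similarity, whose score matrices are integrated by a convex
   weighted sum;
4. cross-validation over causal cells with strict leakage masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import semantics
from .encoding import EncodingSpec, discretize_expression, discretize_pathways, filter_pathways
from .evaluation import (
    auroc,
    mask_positives,
    split_folds,
    split_independent,
)
from .factorization import FitTrace, fit, predict_scores
from .gip import gip_similarity
from .integration import integrate_scores
from .similarity import combine_weighted, similarity_matrix
from .types import AssociationMatrix, ModelConfig, ScoreMatrix, SimilarityMatrix

log = logging.getLogger(__name__)

SOURCES = ("S", "E", "P", "G")


@dataclass
class SimilarityBundle:
    """Label-independent similarity matrices on a fixed universe."""

    ms_sp: SimilarityMatrix
    ms_sm: SimilarityMatrix
    ms_ss: SimilarityMatrix
    ms_s: SimilarityMatrix
    ms_e: SimilarityMatrix
    ms_p: SimilarityMatrix
    ds: SimilarityMatrix


def _feature_strings_for(universe: Sequence[str], strings: Mapping[str, str]) -> dict[str, str]:
    """Restrict/extend a feature-string map onto the miRNA universe.

    MiRNAs absent from a source get an empty string, which the similarity
    builder turns into 0 off-diagonal / 1 diagonal.
    """
    return {m: strings.get(m, "") for m in universe}


def build_similarities(
    md: AssociationMatrix,
    precursor_seqs: Mapping[str, str],
    mature_seqs: Mapping[str, str],
    seed_seqs: Mapping[str, str],
    expression: pd.DataFrame,
    pathways: pd.DataFrame,
    mesh_mapping: Mapping[str, Sequence[str]],
    config: ModelConfig | None = None,
    encoding_spec: EncodingSpec | None = None,
) -> SimilarityBundle:
    """Compute every label-independent similarity matrix on MD's universe."""
    config = config or ModelConfig()
    encoding_spec = encoding_spec or EncodingSpec()
    universe = md.mirna_ids

    ms_sp = similarity_matrix(_feature_strings_for(universe, precursor_seqs))
    ms_sm = similarity_matrix(_feature_strings_for(universe, mature_seqs))
    ms_ss = similarity_matrix(_feature_strings_for(universe, seed_seqs))
    ms_s = combine_weighted([ms_sp, ms_sm, ms_ss], config.seq_weights)
    log.info("sequence similarity built (%d miRNAs)", len(universe))

    expr_strings = discretize_expression(expression, encoding_spec) if not expression.empty else {}
    ms_e = similarity_matrix(_feature_strings_for(universe, expr_strings))

    kept = filter_pathways(pathways, encoding_spec)
    path_strings = discretize_pathways(kept, encoding_spec) if kept.shape[1] else {}
    ms_p = similarity_matrix(_feature_strings_for(universe, path_strings))
    log.info(
        "profile similarities built (%d cell types, %d/%d pathways kept)",
        expression.shape[1] if not expression.empty else 0,
        kept.shape[1],
        pathways.shape[1],
    )

    dag = semantics.build_dag(mesh_mapping)
    ds = semantics.semantic_similarity_matrix(dag, md.disease_ids, config.delta)
    return SimilarityBundle(ms_sp, ms_sm, ms_ss, ms_s, ms_e, ms_p, ds)


def train_all(
    md_train: AssociationMatrix,
    sims: SimilarityBundle,
    config: ModelConfig | None = None,
) -> tuple[dict[str, ScoreMatrix], ScoreMatrix, dict[str, FitTrace]]:
    """Fit one model per miRNA similarity source and integrate the scores.

    The GIP kernel is derived from ``md_train`` itself, so passing a masked
    matrix keeps held-out positives out of every stage.
    """
    config = config or ModelConfig()
    gm = gip_similarity(md_train)
    sources = {"S": sims.ms_s, "E": sims.ms_e, "P": sims.ms_p, "G": gm}
    scores: dict[str, ScoreMatrix] = {}
    traces: dict[str, FitTrace] = {}
    for name, ms in sources.items():
        factors, trace = fit(md_train, ms, sims.ds, config)
        scores[name] = predict_scores(factors)
        traces[name] = trace
        log.info(
            "source %s: %d iterations, objective %.4f -> %.4f",
            name,
            trace.iterations,
            trace.objectives[0],
            trace.objectives[-1],
        )
    integrated = integrate_scores(
        [scores[s] for s in SOURCES], config.integration_weights
    )
    return scores, integrated, traces


@dataclass
class CrossValidationResult:
    """Pooled and per-fold discrimination metrics from k-fold CV."""

    fold_aurocs: list[float]
    pooled_causal_vs_none: float
    macro_causal_vs_none: float
    pooled_causal_vs_noncausal: float | None
    n_folds: int
    masked_matrices: list[AssociationMatrix]

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "fold_aurocs": self.fold_aurocs,
            "pooled_causal_vs_none": self.pooled_causal_vs_none,
            "macro_causal_vs_none": self.macro_causal_vs_none,
            "pooled_causal_vs_noncausal": self.pooled_causal_vs_noncausal,
        }


def cross_validate(
    md: AssociationMatrix,
    sims: SimilarityBundle,
    label_grid: np.ndarray,
    config: ModelConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """K-fold CV over causal cells with per-fold GIP/factorization retraining.

    Per fold, held-out causal cells are zeroed before the GIP kernel and the
    factorizations see the matrix; fold AUROC compares held-out causal
    scores against all unassociated ('none') cells, pooled across folds.
    The causal-vs-non-causal AUROC pools held-out causal scores against
    each fold model's non-causal cell scores.
    """
    config = config or ModelConfig()
    rows, cols = np.nonzero(md.values)
    positives = list(zip(rows.tolist(), cols.tolist()))
    folds = split_folds(positives, n_folds, seed)
    none_mask = label_grid == "none"
    noncausal_mask = label_grid == "non-causal"

    fold_aurocs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    nc_scores: list[np.ndarray] = []
    nc_labels: list[np.ndarray] = []
    masked_matrices: list[AssociationMatrix] = []

    for fold in range(n_folds):
        test_cells = [c for c, f in zip(positives, folds) if f == fold]
        md_train = mask_positives(md, test_cells)
        masked_matrices.append(md_train)
        _, integrated, _ = train_all(md_train, sims, config)
        test_idx = tuple(np.array(x) for x in zip(*test_cells))
        test_scores = integrated.values[test_idx]
        none_scores = integrated.values[none_mask]
        fold_scores = np.concatenate([test_scores, none_scores])
        fold_labels = np.concatenate([np.ones(test_scores.size), np.zeros(none_scores.size)])
        fold_aurocs.append(auroc(fold_scores, fold_labels))
        pooled_scores.append(fold_scores)
        pooled_labels.append(fold_labels)
        if noncausal_mask.any():
            noncausal_scores = integrated.values[noncausal_mask]
            nc_scores.append(np.concatenate([test_scores, noncausal_scores]))
            nc_labels.append(
                np.concatenate([np.ones(test_scores.size), np.zeros(noncausal_scores.size)])
            )
        log.info("fold %d/%d: causal-vs-none AUROC %.3f", fold + 1, n_folds, fold_aurocs[-1])

    pooled = auroc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    pooled_nc = (
        auroc(np.concatenate(nc_scores), np.concatenate(nc_labels)) if nc_scores else None
    )
    return CrossValidationResult(
        fold_aurocs=fold_aurocs,
        pooled_causal_vs_none=pooled,
        macro_causal_vs_none=float(np.mean(fold_aurocs)),
        pooled_causal_vs_noncausal=pooled_nc,
        n_folds=n_folds,
        masked_matrices=masked_matrices,
    )


def independent_test(
    md: AssociationMatrix,
    sims: SimilarityBundle,
    label_grid: np.ndarray,
    fraction: float = 0.2,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Hold out a fraction of causal cells, train on the rest, report AUROCs."""
    rows, cols = np.nonzero(md.values)
    positives = list(zip(rows.tolist(), cols.tolist()))
    _, test_cells = split_independent(positives, fraction, seed)
    md_train = mask_positives(md, test_cells)
    _, integrated, _ = train_all(md_train, sims, config)
    test_idx = tuple(np.array(x) for x in zip(*test_cells))
    test_scores = integrated.values[test_idx]
    none_scores = integrated.values[label_grid == "none"]
    result = {
        "n_test": len(test_cells),
        "causal_vs_none_auroc": auroc(
            np.concatenate([test_scores, none_scores]),
            np.concatenate([np.ones(test_scores.size), np.zeros(none_scores.size)]),
        ),
    }
    noncausal_scores = integrated.values[label_grid == "non-causal"]
    if noncausal_scores.size:
        result["causal_vs_noncausal_auroc"] = auroc(
            np.concatenate([test_scores, noncausal_scores]),
            np.concatenate([np.ones(test_scores.size), np.zeros(noncausal_scores.size)]),
        )
    return result
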