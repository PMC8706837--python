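"""Similarity-regularized matrix factorization of the association matrix.

MiRNAs and diseases are projected into a shared k-dimensional space (columns
of M, k x nm, and D, k x nd); the inner product MD' = M^T D scores each
pair.  The objective fits the known positives to 1 and pulls the factor
Gram matrices toward the given similarity matrices:

    f(M, D) = sum_{(i,j): MD[i,j]=1} (MD'[i,j] - 1)^2
              + lambda1 * ||M^T M - MS||_F^2
              + lambda2 * ||D^T D - DS||_F^2.

Zero cells are unconstrained by the fit term: unobserved pairs are scored
purely through the similarity structure, which is what lets the model rank
unseen causal pairs.  The quartic Gram regularizer rules out closed-form
alternating least squares, so the objective is minimized by alternating
block gradient descent with a backtracking line search; every accepted
update is non-increasing, which the evaluation harness relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    AssociationMatrix,
    ModelConfig,
    ScoreMatrix,
    ShapeError,
    SimilarityMatrix,
)


class DivergenceError(RuntimeError):
    """The objective became non-finite during fitting."""


@dataclass
class LatentFactors:
    """k-dimensional projections of miRNAs (M, k x nm) and diseases (D, k x nd)."""

    M: np.ndarray
    D: np.ndarray
    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.M.ndim != 2 or self.D.ndim != 2 or self.M.shape[0] != self.D.shape[0]:
            raise ShapeError("M and D must be 2-d with a shared latent dimension")
        if self.M.shape[1] != len(self.mirna_ids) or self.D.shape[1] != len(self.disease_ids):
            raise ShapeError("factor shapes do not match their id lists")
        if not (np.isfinite(self.M).all() and np.isfinite(self.D).all()):
            raise ValueError("factors must be finite")

    @property
    def k(self) -> int:
        return self.M.shape[0]


@dataclass
class FitTrace:
    """Objective trajectory of one fit."""

    objectives: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def _check_shapes(md: AssociationMatrix, ms: SimilarityMatrix, ds: SimilarityMatrix) -> None:
    nm, nd = md.shape
    if ms.n != nm:
        raise ShapeError(f"miRNA similarity is {ms.n}x{ms.n}, association has {nm} miRNAs")
    if ds.n != nd:
        raise ShapeError(f"disease similarity is {ds.n}x{ds.n}, association has {nd} diseases")


def objective(
    factors: LatentFactors,
    md: AssociationMatrix,
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    lambda1: float,
    lambda2: float,
) -> float:
    """Fit-plus-regularization objective; the fit sum runs over positives only."""
    _check_shapes(md, ms, ds)
    M, D = factors.M, factors.D
    if M.shape[1] != md.shape[0] or D.shape[1] != md.shape[1]:
        raise ShapeError("factor shapes do not match the association matrix")
    scores = M.T @ D
    pos = md.values == 1.0
    fit = float(((scores[pos] - 1.0) ** 2).sum())
    reg_m = float(np.linalg.norm(M.T @ M - ms.values) ** 2)
    reg_d = float(np.linalg.norm(D.T @ D - ds.values) ** 2)
    return fit + lambda1 * reg_m + lambda2 * reg_d


def gradients(
    factors: LatentFactors,
    md: AssociationMatrix,
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    lambda1: float,
    lambda2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the objective w.r.t. M and D."""
    M, D = factors.M, factors.D
    pos = md.values == 1.0
    resid = np.where(pos, M.T @ D - 1.0, 0.0)  # nm x nd
    grad_m = 2.0 * D @ resid.T + 4.0 * lambda1 * M @ (M.T @ M - ms.values)
    grad_d = 2.0 * M @ resid + 4.0 * lambda2 * D @ (D.T @ D - ds.values)
    return grad_m, grad_d


def fit(
    md_train: AssociationMatrix,
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    config: ModelConfig | None = None,
) -> tuple[LatentFactors, FitTrace]:
    """Alternating block gradient descent with backtracking line search.

    Factors are initialized uniformly in [0, 1/sqrt(k)) from config.seed, so
    initial scores M^T D have magnitude ~1.  Each block update backtracks its
    step until the objective does not increase; fitting stops when the
    relative objective change drops below config.tol.
    """
    config = config or ModelConfig()
    _check_shapes(md_train, ms, ds)
    nm, nd = md_train.shape
    k = config.k
    rng = np.random.default_rng(config.seed)
    scale = 1.0 / np.sqrt(k)
    M = rng.uniform(0.0, scale, size=(k, nm))
    D = rng.uniform(0.0, scale, size=(k, nd))
    factors = LatentFactors(M, D, md_train.mirna_ids, md_train.disease_ids)
    args = (md_train, ms, ds, config.lambda1, config.lambda2)

    obj = objective(factors, *args)
    trace = FitTrace(objectives=[obj])
    # per-block state: last accepted step and previous (iterate, gradient)
    # for the Barzilai-Borwein step proposal
    state: dict[str, dict] = {"M": {"step": 1e-2, "prev": None}, "D": {"step": 1e-2, "prev": None}}

    def _block_step(which: str, obj: float) -> float:
        grad_m, grad_d = gradients(factors, *args)
        grad = grad_m if which == "M" else grad_d
        current = factors.M if which == "M" else factors.D
        st = state[which]
        step = st["step"]
        if st["prev"] is not None:
            # BB1 step from the previous accepted iterate; safeguarded below
            dx = current - st["prev"][0]
            dg = grad - st["prev"][1]
            denom = float((dg * dg).sum())
            if denom > 0:
                bb = abs(float((dx * dg).sum())) / denom
                if np.isfinite(bb) and bb > 0:
                    step = min(max(bb, 1e-10), 1e2)
        for _ in range(60):
            trial = current - step * grad
            if which == "M":
                factors.M = trial
            else:
                factors.D = trial
            new_obj = objective(factors, *args)
            if not np.isfinite(new_obj):
                raise DivergenceError(f"objective non-finite at iteration {trace.iterations}")
            if new_obj <= obj:
                st["step"] = step
                st["prev"] = (current, grad)
                return new_obj
            step /= 2.0
        # no descent found: restore and stall
        if which == "M":
            factors.M = current
        else:
            factors.D = current
        st["step"] = step
        return obj

    for it in range(1, config.max_iters + 1):
        trace.iterations = it
        obj_m = _block_step("M", obj)
        obj_d = _block_step("D", obj_m)
        trace.objectives.append(obj_d)
        rel_change = (obj - obj_d) / max(obj, 1e-12)
        obj = obj_d
        if rel_change < config.tol:
            trace.converged = True
            break
    return factors, trace


def predict_scores(factors: LatentFactors) -> ScoreMatrix:
    """MD' = M^T D on the factors' id grid."""
    return ScoreMatrix(factors.M.T @ factors.D, factors.mirna_ids, factors.disease_ids)
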