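import numpy as np
import pytest

from mircausal.evaluation import auroc
from mircausal.factorization import (
    LatentFactors,
    fit,
    gradients,
    objective,
    predict_scores,
)
from mircausal.types import AssociationMatrix, ModelConfig, SimilarityMatrix


def _md(values):
    values = np.array(values, dtype=float)
    return AssociationMatrix(
        values,
        tuple(f"m{i}" for i in range(values.shape[0])),
        tuple(f"d{j}" for j in range(values.shape[1])),
    )


def _identity_sim(n, prefix):
    return SimilarityMatrix(np.eye(n), tuple(f"{prefix}{i}" for i in range(n)))


def _random_instance(rng, nm=6, nd=5, k=3):
    md = _md((rng.random((nm, nd)) < 0.4).astype(float))
    ms_raw = rng.random((nm, nm))
    ms = (ms_raw + ms_raw.T) / 2
    np.fill_diagonal(ms, 1.0)
    ds_raw = rng.random((nd, nd))
    ds = (ds_raw + ds_raw.T) / 2
    np.fill_diagonal(ds, 1.0)
    ms = SimilarityMatrix(ms, md.mirna_ids)
    ds = SimilarityMatrix(ds, md.disease_ids)
    factors = LatentFactors(
        rng.normal(size=(k, nm)), rng.normal(size=(k, nd)), md.mirna_ids, md.disease_ids
    )
    return md, ms, ds, factors


class TestObjective:
    def test_zero_factors_identity_similarities(self):
        md = _md([[1, 0, 1], [0, 1, 0]])
        factors = LatentFactors(
            np.zeros((2, 2)), np.zeros((2, 3)), md.mirna_ids, md.disease_ids
        )
        ms = _identity_sim(2, "m")
        ds = _identity_sim(3, "d")
        # each positive contributes 1; ||0 - I||_F^2 equals the dimension
        value = objective(factors, md, ms, ds, 1.0, 1.0)
        assert value == pytest.approx(3 + 2 + 3)

    def test_perfect_fit_no_regularization_is_zero(self):
        md = _md([[1.0]])
        factors = LatentFactors(np.array([[1.0]]), np.array([[1.0]]), ("m0",), ("d0",))
        value = objective(factors, md, _identity_sim(1, "m"), _identity_sim(1, "d"), 0.0, 0.0)
        assert value == 0.0

    def test_lambda1_scales_mirna_regularizer_linearly(self, rng):
        md, ms, ds, factors = _random_instance(rng)
        base = objective(factors, md, ms, ds, 0.0, 0.0)
        reg1 = objective(factors, md, ms, ds, 1.0, 0.0) - base
        reg2 = objective(factors, md, ms, ds, 2.0, 0.0) - base
        assert reg2 == pytest.approx(2 * reg1)

    def test_fit_term_only_counts_positive_cells(self, rng):
        md = _md([[1, 0], [0, 0]])
        # scores on zero cells must not affect the fit term
        factors = LatentFactors(
            np.array([[1.0, 99.0]]), np.array([[1.0, 99.0]]), md.mirna_ids, md.disease_ids
        )
        value = objective(factors, md, _identity_sim(2, "m"), _identity_sim(2, "d"), 0.0, 0.0)
        assert value == pytest.approx(0.0)


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        """Analytic gradients agree with finite differences on 6x5 instances."""
        for _ in range(3):
            md, ms, ds, factors = _random_instance(rng)
            lam1, lam2 = 0.7, 1.3
            grad_m, grad_d = gradients(factors, md, ms, ds, lam1, lam2)
            eps = 1e-6
            for grad, attr in ((grad_m, "M"), (grad_d, "D")):
                array = getattr(factors, attr)
                numeric = np.zeros_like(array)
                for idx in np.ndindex(array.shape):
                    orig = array[idx]
                    array[idx] = orig + eps
                    up = objective(factors, md, ms, ds, lam1, lam2)
                    array[idx] = orig - eps
                    down = objective(factors, md, ms, ds, lam1, lam2)
                    array[idx] = orig
                    numeric[idx] = (up - down) / (2 * eps)
                denom = max(np.abs(numeric).max(), 1.0)
                assert np.abs(grad - numeric).max() / denom < 1e-4


class TestFit:
    def test_objective_decreases_on_rank_one_toy(self):
        md = _md([[1, 0], [0, 1]])
        ms = _identity_sim(2, "m")
        ds = _identity_sim(2, "d")
        config = ModelConfig(k=2, lambda1=0.01, lambda2=0.01, max_iters=100, seed=0)
        _, trace = fit(md, ms, ds, config)
        assert trace.objectives[-1] < trace.objectives[0]

    def test_trace_is_monotone_non_increasing(self, rng):
        md, ms, ds, _ = _random_instance(rng, nm=8, nd=6)
        config = ModelConfig(k=4, max_iters=150, seed=3)
        _, trace = fit(md, ms, ds, config)
        diffs = np.diff(trace.objectives)
        assert (diffs <= 1e-9).all()

    def test_same_seed_is_bitwise_deterministic(self, rng):
        md, ms, ds, _ = _random_instance(rng)
        config = ModelConfig(k=3, max_iters=50, seed=42)
        f1, _ = fit(md, ms, ds, config)
        f2, _ = fit(md, ms, ds, config)
        assert (f1.M == f2.M).all() and (f1.D == f2.D).all()

    def test_noiseless_planted_structure_is_recovered(self, rng):
        """With MS/DS equal to the planted factor Grams and positives from
        thresholding the planted scores, fitting at the true k separates
        positive from negative cells perfectly on the training instance."""
        k, nm, nd = 3, 8, 6
        M = np.abs(rng.normal(size=(k, nm)))
        D = np.abs(rng.normal(size=(k, nd)))
        M /= np.linalg.norm(M, axis=0)
        D /= np.linalg.norm(D, axis=0)
        scores = M.T @ D
        threshold = np.quantile(scores, 0.7)
        md = _md((scores > threshold).astype(float))
        ms = SimilarityMatrix(M.T @ M, md.mirna_ids)
        ds = SimilarityMatrix(D.T @ D, md.disease_ids)
        config = ModelConfig(k=k, lambda1=1.0, lambda2=1.0, max_iters=2000, tol=1e-12, seed=5)
        factors, _ = fit(md, ms, ds, config)
        fitted = predict_scores(factors).values
        labels = md.values.ravel()
        assert auroc(fitted.ravel(), labels) == pytest.approx(1.0)


class TestPredictScores:
    def test_rank_one_product_by_hand(self):
        factors = LatentFactors(
            np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]), ("m0", "m1"), ("d0", "d1")
        )
        assert predict_scores(factors).values.tolist() == [[3.0, 4.0], [6.0, 8.0]]

    def test_zero_factors_give_zero_scores(self):
        factors = LatentFactors(np.zeros((2, 3)), np.zeros((2, 2)), ("a", "b", "c"), ("x", "y"))
        assert (predict_scores(factors).values == 0).all()
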