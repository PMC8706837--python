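"""Gaussian interaction profile (GIP) kernel similarity.

Each miRNA's interaction profile IP(i) is its row of the binary association
matrix; similarity is exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth
normalized by the mean squared profile norm, gamma = gamma' / mean(||IP||^2).
Inside cross-validation the kernel must be computed from the training-masked
matrix only, so held-out positives never leak into the similarity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .types import AssociationMatrix, SimilarityMatrix


class DegenerateKernelWarning(UserWarning):
    """All interaction profiles are zero; the kernel collapses to identity."""


def gip_similarity(
    md: AssociationMatrix, gamma_prime: float = 1.0, axis: str = "mirna"
) -> SimilarityMatrix:
    """GIP kernel over rows (miRNAs) or columns (diseases) of MD."""
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    if axis not in ("mirna", "disease"):
        raise ValueError("axis must be 'mirna' or 'disease'")
    profiles = md.values if axis == "mirna" else md.values.T
    ids = md.mirna_ids if axis == "mirna" else md.disease_ids
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        warnings.warn(
            "all interaction profiles are zero; returning identity kernel",
            DegenerateKernelWarning,
        )
        return SimilarityMatrix(np.eye(len(ids)), tuple(ids))
    gamma = gamma_prime / mean_sq_norm
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq_dists)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return SimilarityMatrix(values, tuple(ids))
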