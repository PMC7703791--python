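"""Self-tuning similarity kernels.

Two kernels over Euclidean distances between samples:

* the Zelnik-Manor self-tuning kernel
  ``A_ij = exp(-d^2(s_i, s_j) / (sigma_i sigma_j))``, where ``sigma_i`` is
  the distance from point i to its P-th nearest neighbour (local scale);
* the adaptive density-aware kernel
  ``A_ij = exp(-d^2(s_i, s_j) / (sigma_i sigma_j (CNN_ij + 1)))``, where
  ``CNN_ij`` counts the common members of the two points' S-nearest-
  neighbour sets.  Sharing neighbours inflates the denominator's third
  term and therefore the similarity, strengthening connections inside
  dense regions.

Self is excluded from all nearest-neighbour sets; neighbour ties break by
ascending sample index so results are deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .types import ExpressionMatrix, KernelParams, NumericError, ParameterError, SimilarityGraph

__all__ = [
    "pairwise_distances",
    "local_scale",
    "cnn_counts",
    "adaptive_kernel",
    "zelnik_manor_kernel",
]


def _as_points(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def pairwise_distances(X) -> np.ndarray:
    """Euclidean distance matrix between samples.

    ``X`` is an :class:`ExpressionMatrix` (samples in columns) or a plain
    samples-by-features array.  The result is exactly symmetric with a
    zero diagonal.
    """
    pts = _as_points(X)
    return squareform(pdist(pts, metric="euclidean"))


def _neighbour_order(D: np.ndarray) -> np.ndarray:
    """Per-row neighbour indices by ascending distance, self excluded.

    Ties resolve by ascending sample index (stable sort).
    """
    n = D.shape[0]
    Dx = D.copy()
    np.fill_diagonal(Dx, np.inf)  # push self to the end
    return np.argsort(Dx, axis=1, kind="stable")[:, : n - 1]


def local_scale(D: np.ndarray, P: int) -> np.ndarray:
    """Per-point local scale: distance to the P-th nearest other point.

    Duplicate points make that distance 0, which would blow up the kernel;
    the scale then falls back to the smallest strictly positive neighbour
    distance, and to 1 if every distance from the point is 0.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= P <= n - 1:
        raise ParameterError(f"P={P} outside [1, {n - 1}] for N={n}")
    order = _neighbour_order(D)
    sigma = D[np.arange(n), order[:, P - 1]]
    for i in np.nonzero(sigma == 0)[0]:
        positive = D[i][D[i] > 0]
        sigma[i] = positive.min() if positive.size else 1.0
    return sigma


def cnn_counts(D: np.ndarray, S: int) -> np.ndarray:
    """Common-nearest-neighbour counts: CNN(i,j) = |NN_S(i) & NN_S(j)|.

    NN_S(i) is the set of the S nearest neighbours of point i (self
    excluded).  The matrix is symmetric with entries in [0, S].
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= S <= n - 1:
        raise ParameterError(f"S={S} outside [1, {n - 1}] for N={n}")
    order = _neighbour_order(D)[:, :S]
    member = np.zeros((n, n), dtype=np.int64)
    rows = np.repeat(np.arange(n), S)
    member[rows, order.ravel()] = 1
    return member @ member.T


def _kernel_matrix(D: np.ndarray, sigma: np.ndarray, cnn: np.ndarray) -> np.ndarray:
    """exp(-d^2 / (sigma_i sigma_j (cnn + 1))) with an exact unit diagonal."""
    denom = np.outer(sigma, sigma) * (cnn + 1.0)
    A = np.exp(-(D**2) / denom)
    if not np.isfinite(A).all():
        raise NumericError("non-finite kernel entry (degenerate local scales)")
    np.fill_diagonal(A, 1.0)
    return np.maximum(A, A.T)  # exact symmetry against fp noise


def adaptive_kernel(D: np.ndarray, params: KernelParams = KernelParams(),
                    sample_ids=None) -> SimilarityGraph:
    """Adaptive density-aware kernel (local scales + CNN counts)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    params.validate(n)
    sigma = local_scale(D, params.P)
    cnn = cnn_counts(D, params.S)
    A = _kernel_matrix(D, sigma, cnn)
    ids = list(sample_ids) if sample_ids is not None else [f"s{i + 1}" for i in range(n)]
    return SimilarityGraph(A, ids)


def zelnik_manor_kernel(D: np.ndarray, P: int = 3, sample_ids=None) -> SimilarityGraph:
    """Zelnik-Manor self-tuning kernel (local scales only, no CNN term)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    sigma = local_scale(D, P)
    A = _kernel_matrix(D, sigma, np.zeros((n, n)))
    ids = list(sample_ids) if sample_ids is not None else [f"s{i + 1}" for i in range(n)]
    return SimilarityGraph(A, ids)
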