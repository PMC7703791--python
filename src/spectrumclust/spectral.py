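"""Normalised graph Laplacian, eigendecomposition, embedding and GMM.

The operator used here is L = D^{-1/2} A* D^{-1/2} (D the diagonal degree
matrix of the symmetrised fused graph A*).  Its eigenvalues lie in
[-1, 1] and large eigenvalues correspond to slowly-mixing, cluster-
revealing eigenvectors, so everything downstream orders the spectrum
descending.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from sklearn.mixture import GaussianMixture

from .types import DiffusedGraph, EigenSystem, NumericError

__all__ = ["graph_laplacian", "eigendecompose", "embed_rows", "gmm_cluster"]


def graph_laplacian(Astar) -> np.ndarray:
    """Degree-normalised affinity operator D^{-1/2} A* D^{-1/2}.

    ``Astar`` must already be symmetric and non-negative with positive
    row sums (symmetrise the diffused graph first).
    """
    A = Astar.values if isinstance(Astar, DiffusedGraph) else np.asarray(Astar, float)
    d = A.sum(axis=1)
    if np.any(d <= 0):
        raise NumericError("zero row sum in fused graph; Laplacian undefined")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = A * np.outer(inv_sqrt, inv_sqrt)
    return (L + L.T) / 2.0


def eigendecompose(L: np.ndarray) -> EigenSystem:
    """Full symmetric eigendecomposition, eigenvalues sorted descending.

    Each eigenvector's sign is fixed so its largest-magnitude component
    is positive (first occurrence on ties), making downstream dip
    statistics and GMM fits reproducible.
    """
    L = np.asarray(L, dtype=float)
    if not np.allclose(L, L.T, atol=1e-10):
        raise NumericError("Laplacian is not symmetric within 1e-10")
    w, V = eigh((L + L.T) / 2.0)
    w, V = w[::-1], V[:, ::-1]
    flip = V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0
    V = V * np.where(flip, -1.0, 1.0)
    return EigenSystem(np.ascontiguousarray(w), np.ascontiguousarray(V))


def embed_rows(es: EigenSystem, k: int) -> np.ndarray:
    """Stack the leading k eigenvectors and renormalise each row to unit
    Euclidean length (all-zero rows map to the first basis vector)."""
    X = es.eigenvectors[:, :k]
    norms = np.linalg.norm(X, axis=1)
    Y = np.zeros_like(X)
    nz = norms > 0
    Y[nz] = X[nz] / norms[nz, None]
    Y[~nz, 0] = 1.0
    return Y


def gmm_cluster(
    Y: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    reg_covar: float = 1e-6,
) -> np.ndarray:
    """Cluster embedding rows with a k-component full-covariance Gaussian
    mixture; returns 0-based labels by maximum posterior responsibility.

    A degenerate covariance triggers one retry with 100x stronger
    regularisation before the error propagates.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.isfinite(Y).all():
        raise NumericError("non-finite embedding passed to GMM")
    kwargs = dict(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        tol=1e-6,
        max_iter=300,
        init_params="k-means++",
        random_state=seed,
    )
    try:
        gm = GaussianMixture(reg_covar=reg_covar, **kwargs).fit(Y)
    except (ValueError, np.linalg.LinAlgError):
        gm = GaussianMixture(reg_covar=reg_covar * 100, **kwargs).fit(Y)
    return gm.predict(Y)
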