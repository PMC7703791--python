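"""Multi-view graph combination, kNN sparsification and diffusion.

Per-view affinity graphs over a common sample set are summed with equal
weight, sparsified to each row's Z strongest off-diagonal links (plus the
diagonal, so no row can zero out), row-normalised to a stochastic
operator A, and smoothed by the diffusion recursion

    Q_1 = A,    Q_t = A Q_{t-1} A^T + I   (t = 2..iters)

whose fixed-point structure emphasises affinities supported by many
short graph paths.  This is the efficient equivalent of diffusion on the
tensor-product graph of the views; the iteration is applied literally
with ``A^T`` even though the row-normalised A is asymmetric, and the
result is symmetrised only at the point the spectral stage needs a
symmetric operator.
"""

from __future__ import annotations

import numpy as np

from .types import (
    DiffusedGraph,
    FusionParams,
    InputError,
    NumericError,
    SimilarityGraph,
)

__all__ = [
    "combine_views",
    "knn_sparsify",
    "row_normalize",
    "diffuse",
    "symmetrize",
    "fuse_graphs",
]


def combine_views(graphs: list[SimilarityGraph]) -> SimilarityGraph:
    """Equal-weight elementwise sum of per-view similarity graphs.

    With a single view the input graph is returned unchanged.  All views
    must carry identical sample ids in identical order.
    """
    if not graphs:
        raise InputError("no similarity graphs to combine")
    first = graphs[0]
    for g in graphs[1:]:
        if g.sample_ids != first.sample_ids:
            off = sorted(set(g.sample_ids) ^ set(first.sample_ids)) or ["<order differs>"]
            raise InputError(f"sample ids differ between views: {off}")
    if len(graphs) == 1:
        return first
    total = np.sum([g.values for g in graphs], axis=0)
    return SimilarityGraph(total, list(first.sample_ids))


def knn_sparsify(A: np.ndarray, Z: int) -> np.ndarray:
    """Keep each row's Z largest off-diagonal entries plus the diagonal.

    Output rows have at most Z+1 nonzeros; the matrix may be asymmetric.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    FusionParams(Z=Z).validate(n)
    off = A.copy()
    np.fill_diagonal(off, -np.inf)
    # stable argsort descending: ties keep ascending sample index
    order = np.argsort(-off, axis=1, kind="stable")[:, :Z]
    out = np.zeros_like(A)
    rows = np.repeat(np.arange(n), Z)
    cols = order.ravel()
    out[rows, cols] = A[rows, cols]
    out[np.arange(n), np.arange(n)] = np.diag(A)
    return out


def row_normalize(A: np.ndarray) -> np.ndarray:
    """Scale each row to sum to 1."""
    A = np.asarray(A, dtype=float)
    sums = A.sum(axis=1)
    if np.any(sums <= 0):
        bad = np.nonzero(sums <= 0)[0]
        raise NumericError(f"non-positive row sums at rows {bad.tolist()}")
    return A / sums[:, None]


def diffuse(A: np.ndarray, iters: int = 5) -> np.ndarray:
    """Run the diffusion recursion and return Q_iters.

    ``A`` should be row-stochastic.  ``iters=1`` returns A itself.
    """
    A = np.asarray(A, dtype=float)
    if iters < 1:
        raise NumericError(f"iters={iters} must be >= 1")
    eye = np.eye(A.shape[0])
    Q = A
    for _ in range(2, iters + 1):
        Q = A @ Q @ A.T + eye
        if not np.isfinite(Q).all():
            raise NumericError("non-finite intermediate during diffusion")
    return Q


def symmetrize(A: np.ndarray) -> np.ndarray:
    """(A + A^T) / 2 — used once, before the Laplacian."""
    return (A + A.T) / 2.0


def fuse_graphs(
    graphs: list[SimilarityGraph],
    params: FusionParams = FusionParams(),
    apply_diffusion: bool = True,
) -> DiffusedGraph:
    """Combine -> sparsify -> row-normalise -> diffuse, returning A*.

    ``apply_diffusion=False`` stops after the combination step (used when
    dip-based model selection is run on the undiffused graph).
    """
    combined = combine_views(graphs)
    n = combined.n
    params.validate(n)
    if not apply_diffusion:
        return DiffusedGraph(
            combined.values, list(combined.sample_ids),
            provenance=[f"view{i + 1}" for i in range(len(graphs))],
        )
    A = knn_sparsify(combined.values, params.Z)
    A = row_normalize(A)
    Q = diffuse(A, params.iters)
    return DiffusedGraph(
        Q, list(combined.sample_ids),
        provenance=[f"view{i + 1}" for i in range(len(graphs))],
    )
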