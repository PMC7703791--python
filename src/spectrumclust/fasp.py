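"""Fast approximate spectral clustering (FASP) for large sample counts.

Spectral clustering scales cubically with the number of points, k-means
linearly; FASP therefore compresses N samples to m << N k-means
centroids, runs the full spectral pipeline on the centroids only (all
centroid-stage matrices are m-by-m), and propagates each centroid's
cluster label back to its member samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .pipeline import as_views, spectrum_cluster
from .types import (
    ClusteringResult,
    Compression,
    ExpressionMatrix,
    InputError,
    ParameterError,
)

__all__ = ["compress", "expand_labels", "fasp_cluster"]


def compress(X: ExpressionMatrix, m: int, seed: int = 0) -> Compression:
    """k-means compression of the samples to m centroids.

    Uses k-means++ seeding with 10 restarts; deterministic for a fixed
    seed.  scikit-learn relocates empty clusters during Lloyd updates,
    so every centroid ends up non-empty.
    """
    [X] = as_views(X)
    n = X.n_samples
    if not 1 <= m < n:
        raise ParameterError(f"m={m} must be in [1, N-1] with N={n}")
    km = KMeans(n_clusters=m, n_init=10, init="k-means++", random_state=seed)
    assign = km.fit_predict(X.X)
    return Compression(
        centroids=km.cluster_centers_,
        assignment=pd.Series(assign, index=X.sample_ids, name="centroid"),
        m=m,
    )


def expand_labels(centroid_labels, comp: Compression) -> pd.Series:
    """Propagate per-centroid cluster labels back to all samples."""
    centroid_labels = pd.Series(centroid_labels)
    missing = sorted(set(comp.assignment.unique()) - set(centroid_labels.index))
    if missing:
        raise InputError(f"unlabelled centroids: {missing}")
    return comp.assignment.map(centroid_labels).rename("cluster")


def fasp_cluster(
    X, m: int = 900, seed: int = 0, **pipeline_kwargs
) -> tuple[pd.Series, ClusteringResult, Compression]:
    """Compress to m centroids, cluster them, expand labels.

    Returns (sample labels, the centroid-stage clustering result, the
    compression).  Keyword arguments pass through to
    :func:`spectrum_cluster` for the centroid stage.
    """
    [X] = as_views(X)
    maxK = pipeline_kwargs.get("maxK", 10)
    if m < maxK + 1:
        raise ParameterError(f"m={m} must be at least maxK+1={maxK + 1}")
    comp = compress(X, m, seed=seed)
    centroid_view = ExpressionMatrix.from_points(
        comp.centroids, sample_ids=[f"c{i}" for i in range(m)]
    )
    result = spectrum_cluster(centroid_view, seed=seed, **pipeline_kwargs)
    centroid_labels = pd.Series(
        result.labels.to_numpy(), index=np.arange(m), name="cluster"
    )
    labels = expand_labels(centroid_labels, comp)
    return labels, result, comp
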