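"""Synthetic datasets with ground-truth labels.

Three generator families cover the regimes the clustering method is
designed for:

* ``gaussian_blobs`` — K isotropic Gaussian clusters whose centres sit
  equally spaced on a circle (embedded in the first two of ``dims``
  dimensions) with adjacent centres ``separation * sd`` apart, so a
  single knob moves the data from well-separated to overlapping;
* ``multiview_blobs`` — one shared cluster assignment rendered
  independently in each view: per-view random cluster centres in
  feature space plus independent Gaussian noise, so individual views
  under-resolve the structure at high noise while the fused graph
  recovers it;
* ``nonconvex_shapes`` — two interleaved Archimedean spirals or two
  elongated curved bands ("worms"), the non-Gaussian shapes on which
  eigengap-style selection fails and density-aware kernels matter.

Named presets freeze the knob settings used throughout the test-suite
and acceptance analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ParameterError, SimulationTruth

__all__ = ["gaussian_blobs", "multiview_blobs", "nonconvex_shapes", "preset", "PRESETS"]


def _truth(points: np.ndarray, labels: np.ndarray, k: int, seed: int) -> SimulationTruth:
    ids = [f"s{i + 1}" for i in range(points.shape[0])]
    view = ExpressionMatrix.from_points(points, sample_ids=ids)
    return SimulationTruth(
        views=[view],
        labels=pd.Series(labels, index=ids, name="cluster"),
        k_true=k,
        seed=seed,
    )


def _circle_centres(K: int, dims: int, delta: float) -> np.ndarray:
    """K centres with adjacent spacing delta: equally spaced on a circle in
    the first two dimensions (a line for dims=1, the origin for K=1)."""
    centres = np.zeros((K, dims))
    if K == 1:
        return centres
    if dims == 1:
        centres[:, 0] = np.arange(K) * delta
        return centres
    radius = delta / (2.0 * np.sin(np.pi / K))
    angles = 2.0 * np.pi * np.arange(K) / K
    centres[:, 0] = radius * np.cos(angles)
    centres[:, 1] = radius * np.sin(angles)
    return centres


def gaussian_blobs(
    K: int,
    n_per: int = 50,
    dims: int = 2,
    separation: float = 12.0,
    sd: float = 1.0,
    seed: int = 0,
) -> SimulationTruth:
    """K isotropic Gaussian clusters of n_per points each."""
    if K < 1:
        raise ParameterError(f"K={K} must be >= 1")
    if n_per < 2:
        raise ParameterError(f"n_per={n_per} must be >= 2")
    if separation <= 0 or sd <= 0:
        raise ParameterError("separation and sd must be positive")
    rng = np.random.default_rng(seed)
    centres = _circle_centres(K, dims, separation * sd)
    labels = np.repeat(np.arange(1, K + 1), n_per)
    points = centres[labels - 1] + rng.normal(0.0, sd, size=(K * n_per, dims))
    return _truth(points, labels, K, seed)


def multiview_blobs(
    K: int = 3,
    n: int = 300,
    features_per_view: int = 500,
    n_views: int = 2,
    noise_sd: float = 5.2,
    seed: int = 0,
) -> SimulationTruth:
    """Multi-view Gaussian clusters sharing one cluster assignment.

    Each view draws its own cluster centres with unit-variance feature
    entries and adds independent N(0, noise_sd) noise, so the per-view
    signal-to-noise ratio is 1/noise_sd.  The default noise is
    calibrated to the regime where a single view under-resolves K but
    the fused multi-view graph recovers it.
    """
    if n % K:
        raise ParameterError(f"n={n} must be a multiple of K={K}")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, K + 1), n // K)
    ids = [f"s{i + 1}" for i in range(n)]
    views = []
    for v in range(n_views):
        centres = rng.normal(0.0, 1.0, size=(K, features_per_view))
        pts = centres[labels - 1] + rng.normal(
            0.0, noise_sd, size=(n, features_per_view)
        )
        views.append(ExpressionMatrix.from_points(pts, sample_ids=ids))
    return SimulationTruth(
        views=views,
        labels=pd.Series(labels, index=ids, name="cluster"),
        k_true=K,
        seed=seed,
    )


def nonconvex_shapes(
    kind: str, n: int = 300, noise: float = 0.0, seed: int = 0
) -> SimulationTruth:
    """Two-class non-convex shapes: interleaved spirals or worm-like bands."""
    rng = np.random.default_rng(seed)
    n1 = n // 2
    n2 = n - n1
    if kind == "spirals":
        # two interleaved Archimedean arms (r = 0.5 + 2t, phi = 3*pi*t),
        # the second rotated by pi.  The base pattern is deterministic
        # with even arc-length spacing (s(t) ~ 0.5t + t^2 inverted), so
        # the noiseless preset is a fixed test pattern; jitter is added
        # only through ``noise``.
        pts = []
        for size, flip in ((n1, 1.0), (n2, -1.0)):
            u = (np.arange(size) + 0.5) / size
            t = (-0.5 + np.sqrt(0.25 + 6.0 * u)) / 2.0
            r = 0.5 + 2.0 * t
            phi = 3.0 * np.pi * t
            arm = np.column_stack((flip * r * np.cos(phi), flip * r * np.sin(phi)))
            pts.append(arm)
        points = np.vstack(pts)
    elif kind == "worms":
        # two elongated interlocking crescents, stretched along x
        t1 = rng.uniform(0.0, np.pi, n1)
        t2 = rng.uniform(0.0, np.pi, n2)
        band1 = np.column_stack((2.5 * np.cos(t1), np.sin(t1)))
        band2 = np.column_stack((2.5 - 2.5 * np.cos(t2), 0.5 - np.sin(t2)))
        points = np.vstack((band1, band2))
    else:
        raise ParameterError(f"unsupported shape kind {kind!r}")
    if noise > 0:
        points = points + rng.normal(0.0, noise, size=points.shape)
    labels = np.concatenate((np.ones(n1, dtype=int), np.full(n2, 2)))
    return _truth(points, labels, 2, seed)


#: Frozen generator settings for the regimes exercised by the test-suite.
PRESETS: dict[str, dict] = {
    "blobs5": dict(
        kind="blobs", K=5, n_per=100, dims=2, separation=12.0, sd=1.0
    ),
    "blobs10": dict(
        kind="blobs", K=10, n_per=50, dims=10, separation=7.0, sd=1.0
    ),
    "blobs20": dict(
        kind="blobs", K=20, n_per=50, dims=10, separation=7.0, sd=1.0
    ),
    "multiview3": dict(
        kind="multiview", K=3, n=300, features_per_view=500, n_views=2,
        noise_sd=5.2,
    ),
    "spirals": dict(kind="spirals", n=200, noise=0.0),
    "worms": dict(kind="worms", n=300, noise=0.08),
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationTruth:
    """Generate a named preset dataset (see :data:`PRESETS`)."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = dict(PRESETS[name])
    cfg.update(overrides)
    kind = cfg.pop("kind")
    if kind == "blobs":
        return gaussian_blobs(seed=seed, **cfg)
    if kind == "multiview":
        return multiview_blobs(seed=seed, **cfg)
    return nonconvex_shapes(kind, seed=seed, **cfg)
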