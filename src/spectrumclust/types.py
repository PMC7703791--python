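"""Core data containers shared across the pipeline.

All containers are thin dataclasses around numpy arrays plus ordered
identifier lists; heavy lifting lives in the functional modules.  The
orientation convention for expression data follows the omics standard:
features in rows, samples in columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "KernelParams",
    "SimilarityGraph",
    "FusionParams",
    "DiffusedGraph",
    "EigenSystem",
    "DipSeries",
    "DropSearchParams",
    "KSelection",
    "ClusteringResult",
    "Compression",
    "SimulationTruth",
]


class InputError(ValueError):
    """Invalid or inconsistent user input (missing values, bad IDs...)."""


class ParameterError(ValueError):
    """A tuning parameter is outside its admissible range."""


class NumericError(ArithmeticError):
    """A numeric invariant was violated (non-finite entries, zero rows...)."""


@dataclass
class ExpressionMatrix:
    """Continuous feature-by-sample matrix with ordered identifiers.

    ``values`` has shape ``(n_features, n_samples)``; typically log2
    expression.  Samples are the objects being clustered.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D matrix")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids):
            raise InputError(
                f"{len(self.feature_ids)} feature_ids for {nf} feature rows"
            )
        if ns != len(self.sample_ids):
            raise InputError(
                f"{len(self.sample_ids)} sample_ids for {ns} sample columns"
            )
        if ns < 3:
            raise InputError(f"need at least 3 samples, got {ns}")
        if len(set(self.sample_ids)) != ns:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise InputError(f"duplicate sample_ids: {dupes}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                "missing/non-finite value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def X(self) -> np.ndarray:
        """Samples-by-features view (rows are the points to cluster)."""
        return self.values.T

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.columns), list(df.index))

    @classmethod
    def from_points(
        cls, X: np.ndarray, sample_ids: Optional[Sequence[str]] = None
    ) -> "ExpressionMatrix":
        """Build from a samples-by-features array (the simulators' format)."""
        X = np.asarray(X, dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(X.shape[0])]
        feature_ids = [f"f{j + 1}" for j in range(X.shape[1])]
        return cls(X.T, list(sample_ids), feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class KernelParams:
    """Self-tuning kernel parameters.

    P is the index of the nearest neighbour whose distance sets each
    point's local scale sigma_i; S is the size of the nearest-neighbour
    sets intersected for the common-nearest-neighbour (CNN) count.
    """

    P: int = 3
    S: int = 7

    def validate(self, n: int) -> None:
        if not 1 <= self.P <= n - 1:
            raise ParameterError(f"P={self.P} outside [1, {n - 1}] for N={n}")
        if not 1 <= self.S <= n - 1:
            raise ParameterError(f"S={self.S} outside [1, {n - 1}] for N={n}")


@dataclass
class SimilarityGraph:
    """Square symmetric sample-by-sample affinity matrix, entries in (0, 1]."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.sample_ids):
            raise InputError("similarity matrix shape/id mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class FusionParams:
    """Graph fusion parameters: kNN sparsity Z and diffusion iterations."""

    Z: int = 10
    iters: int = 5

    def validate(self, n: int) -> None:
        if not 1 <= self.Z <= n - 1:
            raise ParameterError(f"Z={self.Z} outside [1, {n - 1}] for N={n}")
        if self.iters < 1:
            raise ParameterError(f"iters={self.iters} must be >= 1")


@dataclass
class DiffusedGraph:
    """Fused similarity after kNN sparsification, row normalisation and
    diffusion.  Generally asymmetric until explicitly symmetrised."""

    values: np.ndarray
    sample_ids: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise NumericError("non-finite entries in diffused graph")


@dataclass
class EigenSystem:
    """Eigenvalues (descending) and aligned eigenvector columns of the
    normalised graph Laplacian."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class DipSeries:
    """Dip statistics per leading eigenvector and consecutive differences.

    ``dips[j-1]`` is z_j, the dip statistic of eigenvector j (1-based,
    eigenvectors ordered by descending eigenvalue).  ``diffs[j-1]`` is
    d_j = z_{j+1} - z_j: the change in multimodality between eigenvectors
    j and j+1, so a large negative d_j at position j supports K = j.
    """

    dips: np.ndarray
    diffs: np.ndarray


@dataclass
class DropSearchParams:
    """Last-substantial-drop search: look-ahead window cmax and the factor
    f by which a later drop must exceed the stored one to replace it."""

    cmax: int = 7
    f: float = 2.0

    def validate(self) -> None:
        if self.cmax < 1:
            raise ParameterError(f"cmax={self.cmax} must be >= 1")
        if self.f <= 1:
            raise ParameterError(f"f={self.f} must be > 1")


@dataclass
class KSelection:
    """A chosen number of clusters with per-candidate diagnostics."""

    k: int
    method: str
    candidates: np.ndarray
    scores: np.ndarray  # eigengaps (per candidate K) or dip diffs d_j

    def diagnostics_frame(self) -> pd.DataFrame:
        col = "eigengap" if self.method == "eigengap" else "dip_diff"
        return pd.DataFrame({"candidate_k": self.candidates, col: self.scores})


@dataclass
class ClusteringResult:
    """Labels plus the fused similarity, spectral embedding and K diagnostics."""

    labels: pd.Series  # sample_id -> cluster index in 1..K
    k: int
    k_selection: KSelection
    embedding: np.ndarray
    fused_graph: DiffusedGraph
    kernel_params: KernelParams

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise InputError("duplicate sample ids in labels")


@dataclass
class Compression:
    """k-means compression of a dataset to m centroids (FASP stage 1)."""

    centroids: np.ndarray  # m x n_features
    assignment: pd.Series  # sample_id -> centroid index 0..m-1
    m: int


@dataclass
class SimulationTruth:
    """A simulated dataset with ground-truth cluster labels."""

    views: list[ExpressionMatrix]
    labels: pd.Series  # sample_id -> true cluster 1..K
    k_true: int
    seed: int

    @property
    def X(self) -> ExpressionMatrix:
        """The single view, for single-view simulations."""
        if len(self.views) != 1:
            warnings.warn("multi-view simulation: returning the first view")
        return self.views[0]
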