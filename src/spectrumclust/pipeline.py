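"""End-to-end density-aware spectral clustering pipeline.

Order of operations: per-view adaptive kernels -> equal-weight graph
combination -> kNN sparsification -> row normalisation -> diffusion ->
symmetrisation -> normalised graph Laplacian -> eigendecomposition ->
K selection (eigengap, multimodality gap, or fixed) -> unit-row
eigenvector embedding -> Gaussian-mixture clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fusion import fuse_graphs, symmetrize
from .kernels import adaptive_kernel, pairwise_distances, zelnik_manor_kernel
from .selection import (
    eigengap_k,
    last_substantial_drop,
    multimodality_diffs,
    tune_kernel,
)
from .spectral import eigendecompose, embed_rows, gmm_cluster, graph_laplacian
from .types import (
    ClusteringResult,
    DiffusedGraph,
    DropSearchParams,
    EigenSystem,
    ExpressionMatrix,
    FusionParams,
    InputError,
    KernelParams,
    KSelection,
    ParameterError,
)

__all__ = ["spectrum_cluster", "estimate_k", "as_views", "align_views"]


def as_views(views) -> list[ExpressionMatrix]:
    """Coerce the accepted input forms to a list of ExpressionMatrix."""
    if isinstance(views, ExpressionMatrix):
        return [views]
    if isinstance(views, (np.ndarray, pd.DataFrame)):
        return [
            ExpressionMatrix.from_dataframe(views)
            if isinstance(views, pd.DataFrame)
            else ExpressionMatrix.from_points(views)
        ]
    out = []
    for v in views:
        out.extend(as_views(v))
    if not out:
        raise InputError("no input views")
    return out


def align_views(views: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Reorder every view's samples to match the first view, by sample id."""
    first = views[0]
    aligned = [first]
    ref = first.sample_ids
    for v in views[1:]:
        if v.sample_ids == ref:
            aligned.append(v)
            continue
        missing = sorted(set(ref) ^ set(v.sample_ids))
        if missing:
            raise InputError(f"sample ids not shared across views: {missing}")
        pos = [v.sample_ids.index(s) for s in ref]
        aligned.append(
            ExpressionMatrix(v.values[:, pos], list(ref), list(v.feature_ids))
        )
    return aligned


def _build_graphs(views, kernel_params: KernelParams, kernel: str):
    builders = {
        "adaptive": lambda D, ids: adaptive_kernel(D, kernel_params, sample_ids=ids),
        "zelnik": lambda D, ids: zelnik_manor_kernel(D, kernel_params.P, sample_ids=ids),
    }
    if kernel not in builders:
        raise ParameterError(f"unknown kernel {kernel!r}; choose adaptive or zelnik")
    return [
        builders[kernel](pairwise_distances(v), v.sample_ids) for v in views
    ]


def _fused_eigensystem(
    views: list[ExpressionMatrix],
    kernel_params: KernelParams,
    fusion_params: FusionParams,
    kernel: str,
    apply_diffusion: bool,
) -> tuple[DiffusedGraph, EigenSystem]:
    graphs = _build_graphs(views, kernel_params, kernel)
    fused = fuse_graphs(graphs, fusion_params, apply_diffusion=apply_diffusion)
    L = graph_laplacian(symmetrize(fused.values))
    return fused, eigendecompose(L)


def _select_k(
    method: str,
    es: EigenSystem,
    maxK: int,
    k_fixed,
    drop_params: DropSearchParams,
) -> KSelection:
    if method == "eigengap":
        return eigengap_k(es.eigenvalues, maxK=maxK)
    if method == "dip":
        series = multimodality_diffs(es, maxK=maxK)
        return last_substantial_drop(series, drop_params)
    if method == "fixed":
        if k_fixed is None:
            raise ParameterError("method='fixed' requires k_fixed")
        return KSelection(
            k=int(k_fixed), method="fixed",
            candidates=np.array([int(k_fixed)]), scores=np.array([np.nan]),
        )
    raise ParameterError(f"unknown method {method!r}")


def spectrum_cluster(
    views,
    method: str = "eigengap",
    k_fixed: int | None = None,
    kernel_params: KernelParams = KernelParams(),
    fusion_params: FusionParams = FusionParams(),
    maxK: int = 10,
    seed: int = 0,
    kernel: str = "adaptive",
    tune: bool = False,
    diffusion: bool = True,
) -> ClusteringResult:
    """Run the full pipeline and return labels plus diagnostics.

    Parameters
    ----------
    views
        One feature-by-sample :class:`ExpressionMatrix` (or samples-by-
        features array) or a list of them sharing the same samples.
    method
        ``eigengap`` (default), ``dip`` (multimodality gap) or ``fixed``
        (requires ``k_fixed``).
    tune
        For the dip method only: search the kernel parameter P over
        1..10 by maximising the multimodality gap before clustering.
    diffusion
        Apply kNN sparsification + diffusion to the combined graph.
        Disabling it is only meaningful for the dip method, where the
        diffusion step is optional.
    """
    view_list = align_views(as_views(views))
    n = view_list[0].n_samples
    if not 2 <= maxK <= n - 1:
        raise ParameterError(f"maxK={maxK} outside [2, {n - 1}] for N={n}")

    kp = kernel_params
    if tune:
        if method != "dip":
            raise ParameterError("kernel tuning applies to the dip method only")
        kp, _ = tune_kernel(view_list, S=kernel_params.S, maxK=maxK)

    fused, es = _fused_eigensystem(
        view_list, kp, fusion_params, kernel, apply_diffusion=diffusion
    )
    selection = _select_k(method, es, maxK, k_fixed, DropSearchParams())
    k = selection.k
    Y = embed_rows(es, k)
    raw = gmm_cluster(Y, k, seed=seed)
    labels = pd.Series(raw + 1, index=view_list[0].sample_ids, name="cluster")
    return ClusteringResult(
        labels=labels,
        k=k,
        k_selection=selection,
        embedding=Y,
        fused_graph=fused,
        kernel_params=kp,
    )


def estimate_k(
    views,
    method: str = "eigengap",
    kernel_params: KernelParams = KernelParams(),
    fusion_params: FusionParams = FusionParams(),
    maxK: int = 10,
    kernel: str = "adaptive",
    tune: bool = False,
    diffusion: bool = True,
) -> KSelection:
    """K selection only — the pipeline up to but excluding the GMM fit."""
    view_list = align_views(as_views(views))
    n = view_list[0].n_samples
    if not 2 <= maxK <= n - 1:
        raise ParameterError(f"maxK={maxK} outside [2, {n - 1}] for N={n}")
    kp = kernel_params
    if tune:
        if method != "dip":
            raise ParameterError("kernel tuning applies to the dip method only")
        kp, _ = tune_kernel(view_list, S=kernel_params.S, maxK=maxK)
    _, es = _fused_eigensystem(
        view_list, kp, fusion_params, kernel, apply_diffusion=diffusion
    )
    return _select_k(method, es, maxK, None, DropSearchParams())
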