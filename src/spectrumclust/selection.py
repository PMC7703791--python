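"""Automatic choice of the number of clusters K.

Two heuristics over the spectrum of the normalised graph Laplacian:

* **eigengap** — K* = argmax over n = 2..maxK of (lambda_n - lambda_{n+1})
  with eigenvalues sorted descending; reliable for near-block-diagonal
  (Gaussian-blob-like) graphs.
* **multimodality gap** — each leading eigenvector is scored with the
  Hartigan-Hartigan dip statistic z_j (departure of its component
  distribution from unimodality).  Informative eigenvectors are
  multimodal; past the true K the dip collapses, so the consecutive
  differences d_j = z_{j+1} - z_j show a large negative drop at j = K.
  Because noise can produce early local drops, the selected drop is the
  *last substantial* one: a stored drop is replaced by a later drop at
  least f-fold more negative, searching up to cmax positions ahead.
  This heuristic also handles non-convex (non-Gaussian) structures and
  supports tuning the kernel's neighbour parameter P by maximising the
  multimodality gap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .fusion import combine_views
from .kernels import _kernel_matrix, cnn_counts, local_scale, pairwise_distances
from .spectral import eigendecompose, graph_laplacian
from .types import (
    DipSeries,
    DropSearchParams,
    EigenSystem,
    KernelParams,
    KSelection,
    ParameterError,
)

__all__ = [
    "eigengap_k",
    "dip_statistic",
    "multimodality_diffs",
    "last_substantial_drop",
    "tune_kernel",
]


def eigengap_k(eigenvalues: np.ndarray, maxK: int = 10) -> KSelection:
    """Pick K maximising the consecutive eigenvalue gap, K in 2..maxK.

    Ties break toward the smaller K.  ``eigenvalues`` must be sorted
    descending and contain at least maxK+1 entries.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if maxK < 2:
        raise ParameterError(f"maxK={maxK} must be >= 2")
    if ev.size < maxK + 1:
        raise ParameterError(f"need {maxK + 1} eigenvalues, got {ev.size}")
    candidates = np.arange(2, maxK + 1)
    gaps = ev[candidates - 1] - ev[candidates]
    k = int(candidates[int(np.argmax(gaps))])
    return KSelection(k=k, method="eigengap", candidates=candidates, scores=gaps)


# ---------------------------------------------------------------------------
# Hartigan & Hartigan dip statistic
# ---------------------------------------------------------------------------

def dip_statistic(x: np.ndarray) -> float:
    """Dip statistic: sup-norm distance between the sample's empirical CDF
    and the closest unimodal CDF.

    Computed with the modal-interval algorithm: the greatest convex
    minorant (GCM) and least concave majorant (LCM) of the empirical CDF
    are fitted over a shrinking interval [low, high]; the interval
    contracts to the modal interval while the largest ECDF deviation from
    the one-sided fits outside it accumulates into the dip.  Values lie
    in [1/(2n), 0.25]; a constant sample returns the degenerate limit 0.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 4:
        raise ParameterError(f"dip statistic needs >= 4 observations, got {n}")
    if x[-1] == x[0]:
        warnings.warn("constant sample: dip statistic is 0")
        return 0.0
    return _dip_sorted(x)


def _dip_sorted(x: np.ndarray) -> float:
    """Core dip computation on a sorted sample with x[0] < x[-1].

    1-based index arrays mirror the classic published algorithm: ``mn``
    and ``mj`` hold, for every point, the previous/next touch point of
    the GCM/LCM chain of the full sample.
    """
    n = x.size
    xx = np.empty(n + 1)
    xx[1:] = x
    x = xx

    # GCM predecessor chain (convexity in (x, rank) space)
    mn = np.empty(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # LCM successor chain (concavity)
    mj = np.empty(n + 1, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in ECDF-count units; divided by 2n on return

    gcm = np.empty(n + 2, dtype=np.int64)
    lcm = np.empty(n + 2, dtype=np.int64)
    while True:
        # change points of the GCM on [low, high], listed high -> low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        # change points of the LCM on [low, high], listed low -> high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i

        if l_gcm != 2 or l_lcm != 2:
            # largest vertical distance between GCM and LCM fits
            ix, iv, d = l_gcm - 1, 2, 0.0
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next corner upward is an LCM corner: measure there
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    # next corner upward is a GCM corner
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # max ECDF deviation from the GCM below the modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # max ECDF deviation from the LCM above the modal interval
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break  # modal interval stopped shrinking
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


def multimodality_diffs(es: EigenSystem, maxK: int = 10) -> DipSeries:
    """Dip statistics z_1..z_maxK of the leading eigenvectors and their
    consecutive differences d_j = z_{j+1} - z_j (length maxK-1)."""
    n = es.eigenvectors.shape[0]
    if maxK < 3:
        raise ParameterError(f"maxK={maxK} must be >= 3 for the dip series")
    if maxK > n:
        raise ParameterError(f"maxK={maxK} exceeds the number of eigenvectors {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant leading eigenvector is routine
        dips = np.array(
            [dip_statistic(es.eigenvectors[:, j]) for j in range(maxK)]
        )
    return DipSeries(dips=dips, diffs=np.diff(dips))


def last_substantial_drop(
    series: DipSeries, params: DropSearchParams = DropSearchParams()
) -> KSelection:
    """Select K as the position of the last substantial multimodality drop.

    d_1 (the drop from the first to the second eigenvector) is skipped as
    non-informative.  d_2 is stored as the default drop; scanning
    onwards, a later drop replaces the stored one when it is at least
    f-fold more negative, and the scan stops once it has moved more than
    cmax positions past the stored drop.  The chosen position j gives
    K = j.
    """
    params.validate()
    d = np.asarray(series.diffs, dtype=float)
    if d.size < 2:
        raise ParameterError("need at least 2 dip differences")
    candidates = np.arange(1, d.size + 1)
    if np.all(d[1:] >= 0):
        warnings.warn("no negative multimodality drop found; defaulting to K=2")
        return KSelection(k=2, method="dip", candidates=candidates, scores=d)
    j_min, d_min = 2, d[1]  # 1-based: d_2
    for j in range(3, d.size + 1):
        if j - j_min > params.cmax:
            break  # window of cmax positions past the stored drop exhausted
        dj = d[j - 1]
        if params.f * d_min > dj:
            j_min, d_min = j, dj
    return KSelection(k=j_min, method="dip", candidates=candidates, scores=d)


def tune_kernel(
    views,
    P_range=range(1, 11),
    S: int = 7,
    maxK: int = 10,
) -> tuple[KernelParams, pd.DataFrame]:
    """Tune the kernel's local-scale parameter P by the multimodality gap.

    For each P, the per-view adaptive kernels are built and summed, the
    graph Laplacian of the combined graph is eigendecomposed, and the
    minimum dip difference min(D^P) is recorded; the P with the most
    negative minimum (largest gap anywhere in the series) wins, ties
    toward smaller P.  Returns the winning params and a diagnostics
    table.
    """
    from .pipeline import as_views  # local import to avoid a cycle

    view_list = as_views(views)
    dists = [pairwise_distances(v) for v in view_list]
    cnns = [cnn_counts(D, S) for D in dists]
    rows = []
    best_p, best_score = None, np.inf
    for P in P_range:
        mats = []
        for D, cnn in zip(dists, cnns):
            sigma = local_scale(D, P)
            mats.append(_kernel_matrix(D, sigma, cnn))
        combined = np.sum(mats, axis=0)
        es = eigendecompose(graph_laplacian(combined))
        series = multimodality_diffs(es, maxK=maxK)
        score = float(series.diffs.min())
        rows.append({"P": P, "min_dip_diff": score})
        if score < best_score:
            best_p, best_score = P, score
    diagnostics = pd.DataFrame(rows)
    return KernelParams(P=int(best_p), S=S), diagnostics
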