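"""Independent brute-force oracles used by the test-suite.

Each function recomputes a pipeline quantity by the most direct route
available (explicit loops, closed forms, or LP enumeration), sharing no
code with the implementation under test.
"""

import numpy as np
from scipy.optimize import linprog


def distance_loop(X: np.ndarray) -> np.ndarray:
    """Per-pair sqrt-of-squares Euclidean distances."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    return D


def cnn_loop(D: np.ndarray, S: int) -> np.ndarray:
    """Explicit set-intersection CNN counts."""
    n = D.shape[0]
    sets = []
    for i in range(n):
        order = sorted((D[i, j], j) for j in range(n) if j != i)
        sets.append({j for _, j in order[:S]})
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            out[i, j] = len(sets[i] & sets[j])
    return out


def kernel_scalar(D: np.ndarray, sigma: np.ndarray, cnn: np.ndarray) -> np.ndarray:
    """Entry-by-entry three-term kernel formula."""
    n = D.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = np.exp(-D[i, j] ** 2 / (sigma[i] * sigma[j] * (cnn[i, j] + 1)))
    return A


def sparsify_rowsort(A: np.ndarray, Z: int) -> np.ndarray:
    """Per-row sort-based top-Z (plus diagonal) sparsification."""
    n = A.shape[0]
    out = np.zeros_like(A)
    for i in range(n):
        offs = sorted(((A[i, j], -j) for j in range(n) if j != i), reverse=True)
        keep = [-negj for _, negj in offs[:Z]]
        for j in keep:
            out[i, j] = A[i, j]
        out[i, i] = A[i, i]
    return out


def diffusion_loop(A: np.ndarray, iters: int) -> np.ndarray:
    """Naive recurrence Q_1 = A, Q_t = A Q_{t-1} A^T + I."""
    Q = A.copy()
    for _ in range(iters - 1):
        Q = A @ Q @ A.T + np.eye(A.shape[0])
    return Q


def laplacian_scalar(A: np.ndarray) -> np.ndarray:
    """Entrywise A_ij / sqrt(rowsum_i * rowsum_j)."""
    n = A.shape[0]
    r = A.sum(axis=1)
    L = np.zeros_like(A)
    for i in range(n):
        for j in range(n):
            L[i, j] = A[i, j] / np.sqrt(r[i] * r[j])
    return L


def eigengap_scan(eigenvalues: np.ndarray, maxK: int) -> int:
    """Exhaustive argmax of consecutive gaps over candidates 2..maxK."""
    best_k, best_gap = None, -np.inf
    for n_ in range(2, maxK + 1):
        gap = eigenvalues[n_ - 1] - eigenvalues[n_]
        if gap > best_gap:
            best_k, best_gap = n_, gap
    return best_k


def drop_replay(diffs: np.ndarray, cmax: int, f: float) -> int:
    """Window-by-window replay of the last-substantial-drop rules.

    Skips d_1; starts from the stored default d_2; repeatedly looks for
    the first position within cmax steps past the stored drop that is
    f-fold more negative, until no such position exists.  All drops
    non-negative past d_1 defaults to K = 2.
    """
    d = np.asarray(diffs, dtype=float)
    if np.all(d[1:] >= 0):
        return 2
    stored = 2
    while True:
        hi = min(stored + cmax, d.size)
        replacement = None
        for j in range(stored + 1, hi + 1):
            if f * d[stored - 1] > d[j - 1]:
                replacement = j
                break
        if replacement is None:
            return stored
        stored = replacement


def dip_lp(x: np.ndarray) -> float:
    """Dip statistic by LP: minimal sup-norm distance between the ECDF
    and a piecewise-linear unimodal CDF, enumerating mode placements.

    For unique knots u_0..u_{K-1} with cumulative ECDF chi_k = F(u_k)
    and clo_k = F(u_k^-), a candidate fit G is parameterised by its knot
    values; G must be convex before the mode and concave after it, with
    a jump allowed only at the mode.  Mode placements: strictly inside a
    gap between knots (where a jump is possible but the continuous rest
    of the gap segment must respect one neighbouring slope bound: gap
    chord slope >= min(last convex slope, first concave slope), a
    disjunction solved as two LPs) or exactly at a knot (an atom, with a
    separate left-limit variable).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    K = u.size
    if K < 2:
        return 0.0
    chi = np.cumsum(counts) / n
    clo = np.concatenate(([0.0], chi[:-1]))
    best = np.inf

    def solve(A_ub, b_ub, nvar):
        c = np.zeros(nvar)
        c[-1] = 1.0
        bounds = [(0, 1)] * (nvar - 1) + [(0, None)]
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=bounds, method="highs")
        return res.fun if res.status == 0 else np.inf

    def band_rows(nvar, t_ix, skip_upper=None):
        rows, rhs = [], []
        for k in range(K):
            r = np.zeros(nvar); r[k] = -1; r[t_ix] = -1
            rows.append(r); rhs.append(-chi[k])      # g_k >= chi_k - t
            if k != skip_upper:
                r = np.zeros(nvar); r[k] = 1; r[t_ix] = -1
                rows.append(r); rhs.append(clo[k])   # g_k <= clo_k + t
        for k in range(K - 1):
            r = np.zeros(nvar); r[k] = 1; r[k + 1] = -1
            rows.append(r); rhs.append(0.0)          # monotone
        return rows, rhs

    def convex_row(nvar, i, j, k):
        # slope(i->j) <= slope(j->k)
        dx0, dx1 = u[j] - u[i], u[k] - u[j]
        r = np.zeros(nvar)
        r[i] = -dx1
        r[j] = dx1 + dx0
        r[k] = -dx0
        return r

    # mode strictly inside the gap below knot s (s=0: all concave;
    # s=K: all convex)
    for s in range(K + 1):
        nvar = K + 1
        t_ix = K
        A, b = band_rows(nvar, t_ix)
        for i in range(1, s - 1):
            A.append(convex_row(nvar, i - 1, i, i + 1)); b.append(0.0)
        for i in range(s + 1, K - 1):
            A.append(-convex_row(nvar, i - 1, i, i + 1)); b.append(0.0)
        variants = []
        if 2 <= s <= K - 1:
            variants.append(convex_row(nvar, s - 2, s - 1, s))
        if 1 <= s <= K - 2:
            variants.append(-convex_row(nvar, s - 1, s, s + 1))
        for var in variants or [None]:
            Av, bv = list(A), list(b)
            if var is not None:
                Av.append(var); bv.append(0.0)
            best = min(best, solve(Av, bv, nvar))

    # mode exactly at knot k0 (atom): left-limit variable a
    for k0 in range(K):
        nvar = K + 2
        a_ix, t_ix = K, K + 1
        A, b = band_rows(nvar, t_ix, skip_upper=k0)
        r = np.zeros(nvar); r[a_ix] = 1; r[t_ix] = -1
        A.append(r); b.append(clo[k0])               # a <= clo_{k0} + t
        r = np.zeros(nvar); r[a_ix] = -1; r[t_ix] = -1
        A.append(r); b.append(-clo[k0])              # a >= clo_{k0} - t
        r = np.zeros(nvar); r[a_ix] = 1; r[k0] = -1
        A.append(r); b.append(0.0)                   # a <= g_{k0}
        if k0 >= 1:
            r = np.zeros(nvar); r[k0 - 1] = 1; r[a_ix] = -1
            A.append(r); b.append(0.0)               # g_{k0-1} <= a
        for i in range(1, k0 - 1):
            A.append(convex_row(nvar, i - 1, i, i + 1)); b.append(0.0)
        if k0 >= 2:
            # last convex link: slope(k0-2 -> k0-1) <= slope(k0-1 -> a)
            dx0 = u[k0 - 1] - u[k0 - 2]
            dx1 = u[k0] - u[k0 - 1]
            r = np.zeros(nvar)
            r[k0 - 2] = -dx1; r[k0 - 1] = dx1 + dx0; r[a_ix] = -dx0
            A.append(r); b.append(0.0)
        for i in range(k0 + 1, K - 1):
            A.append(-convex_row(nvar, i - 1, i, i + 1)); b.append(0.0)
        best = min(best, solve(A, b, nvar))

    return float(best)
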