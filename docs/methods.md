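# Methods

This note records the model, the numerical conventions and the design
choices behind `spectrumclust`, in the spirit of a package reference
manual: everything here describes what the code does and why, not
empirical claims beyond what the test-suite and `scripts/acceptance.py`
themselves compute.

## Model and assumptions

The method is spectral clustering over a density-aware affinity graph.
Its working assumptions are:

* samples live in a continuous feature space where Euclidean distance is
  meaningful (in omics practice: log-transformed, optionally
  variance-filtered expression values — the kernel applies no internal
  centering or scaling, by design);
* cluster structure is expressible as strongly connected blocks of a
  kNN-style graph — compact blobs and connected non-convex manifolds
  both qualify; clusters that overlap heavily in density do not;
* in multi-view data, all views share the same samples and the same
  underlying partition; views are combined with equal weight, so a view
  that carries a genuinely different structure should be excluded by the
  analyst beforehand.

### Affinity

`A_ij = exp(−d²(s_i,s_j) / (σ_i σ_j (CNN_ij + 1)))` with local scale
`σ_i` = distance to the P-th nearest neighbour and `CNN_ij` = size of
the intersection of the two S-nearest-neighbour sets. Self is excluded
from every neighbour set: the "P-th nearest neighbour" is the P-th
*other* point, and a point is not its own common neighbour. Including
self would only shift P and add a constant to CNN. Neighbour ties are
broken by ascending sample index (stable argsort), making every
downstream quantity deterministic.

Degenerate geometry: if the P-th neighbour distance is 0 (duplicated
points), σ_i falls back to the smallest strictly positive distance from
that point, and to 1 if the point coincides with every other point.
This keeps the kernel finite while leaving exact duplicates maximally
similar (A = 1).

### Fusion and diffusion

Per-view graphs are summed (a single view passes through unchanged),
sparsified per row to the Z largest off-diagonal entries *plus the
diagonal*, row-normalised, and diffused via `Q_1 = A`,
`Q_t = A Q_{t−1} Aᵀ + I`. Retaining the diagonal guarantees positive
row sums (row normalisation is always well defined) and composes
naturally with the +I term of the diffusion. The recursion is applied
literally with `Aᵀ` even though row-normalised A is asymmetric, and no
re-symmetrisation happens between iterations; the final `A*` is
symmetrised once, as `(A* + A*ᵀ)/2`, immediately before the Laplacian —
the spectral stage assumes a symmetric operator, and degree
normalisation absorbs the scale the diffusion introduces.

A note on what diffusion does and does not do: it consolidates
within-block connectivity and enlarges the spectral gap that separates
the block structure (this is tested directly), but it does *not*
decrease the mean between-block affinity relative to the mean
within-block affinity — the +I recursion spreads a thin layer of mass
everywhere. Its benefit is spectral, not visible in simple affinity
averages.

### Spectral stage

`L = D^{−1/2} A* D^{−1/2}` (no subtraction from I, so informative
eigenvalues are the *largest*), full symmetric eigendecomposition via
LAPACK, eigenvalues sorted descending. Eigenvector sign is fixed by
making the largest-magnitude component positive — eigen-solvers return
arbitrary signs, and both the dip statistics and the GMM initialisation
must be reproducible. The embedding stacks the top-K eigenvectors and
renormalises each row to unit length; an all-zero row (possible only on
degenerate graphs) maps to the first basis vector instead of NaN.

GMM configuration (the literature underdetermines this): full
covariance, k-means++ initialisation, 10 restarts, tolerance 1e−6,
covariance regularisation 1e−6, fixed seed; a degenerate covariance
triggers one retry at 100× regularisation. Full covariance matters
because spectral embeddings produce elongated, rotated clusters.

## Choosing K

**Eigengap** — `K* = argmax_{n=2..maxK} (λ_n − λ_{n+1})`, ties toward
smaller n. For a graph with k disconnected blocks exactly k eigenvalues
equal 1, so the gap at n = k is the dominant one.

**Multimodality gap** — dip statistics z_1..z_maxK of the leading
eigenvectors; differences d_j = z_{j+1} − z_j. Indexing convention: d_j
is the drop *between eigenvectors j and j+1*, and selecting the drop at
position j yields K = j (the five-blob simulation drops between
eigenvectors five and six, giving K = 5). The search skips d_1 (the
first-to-second drop is structurally uninformative), stores d_2 as the
default, and scanning from d_3 replaces the stored drop whenever
`f·d_min > d_j` (with d_min < 0 this means "at least f-fold more
negative"), resetting the look-ahead; the scan stops once it is more
than cmax positions past the stored drop. Defaults cmax = 7, f = 2.
The replacement rule is applied literally also when d_min ≥ 0; the
fully degenerate case (no negative drop after d_1) returns K = 2 with a
warning. A simple argmin over the series is deliberately *not* used —
fixtures in the test-suite show argmin landing on an early local drop
that the last-substantial-drop rule correctly skips.

**Kernel tuning** (dip method only): P runs over 1..10; for each P the
combined (undiffused) kernel graph's Laplacian eigenvectors are scored
and min(D^P) recorded — the literal minimum over the whole difference
series, including d_1; the P with the most negative minimum wins, ties
toward smaller P. S stays fixed during tuning. The eigengap path always
uses the fixed defaults P = 3, S = 7. After tuning, the selected kernel
re-enters the standard sparsify/normalise/diffuse route (diffusion for
the dip path is on by default and can be disabled, since the dip
analysis itself is meaningful on the undiffused graph).

**Dip statistic** — implemented from scratch with the modal-interval
algorithm: greatest-convex-minorant and least-concave-majorant chains
of the empirical CDF over a shrinking interval, the maximum ECDF
deviation outside the modal interval accumulating into the dip (final
division by 2n; values in [1/(2n), 1/4]; a constant sample returns the
limit 0 with a warning). The implementation is verified against an
independent linear-programming oracle that minimises the sup-norm
distance between the ECDF and an explicitly parameterised
piecewise-linear unimodal CDF, enumerating every mode placement
(between-knot gaps and atoms at knots). The two routes agree to 1e−9 on
exhaustive small tied samples and random continuous/bimodal/tied
samples up to n = 100.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| P | 3 | local-scale neighbour index; smaller = more local structure |
| S | 7 | CNN neighbour-set size; density sensitivity of the kernel |
| Z | 10 | kNN sparsity of the fused graph |
| iters | 5 | diffusion iterations |
| maxK | 10 | largest candidate K scanned (raise for >9 expected clusters; the dip series of length maxK supports K up to maxK−1) |
| cmax, f | 7, 2 | last-substantial-drop look-ahead and replacement factor |
| m (`--centroids`) | 900 | FASP compression size; the spectral stage then costs O(m³) independent of N |
| keep_fraction | 0.5 | coefficient-of-variation feature filter (`--cv-filter`), the conventional top-50 % most variable features |

All are surfaced through both the library API and the CLI; P, S, Z,
iters, cmax and f carry the defaults used throughout the validation
suite.

## Synthetic data: what it emulates, what it does not

The generators produce the regimes the method is designed around, not
realistic omics data: no count noise, no batch effects, no heavy tails,
no missing values, no correlated features beyond the planted structure.
Passing the simulation suite therefore demonstrates that the *algorithm*
behaves as designed in its intended regimes — it does not certify
performance on any particular real dataset.

* `gaussian_blobs` — K isotropic Gaussians, centres equally spaced on a
  circle (embedded in the first two of `dims` dimensions) with adjacent
  spacing `separation·sd`; one knob interpolates well-separated to
  overlapping. Presets: `blobs5` (K=5, 100/cluster, 2-D, spacing 12σ —
  the clearly separated regime; 100 points per cluster keeps the Z=10
  kNN graph internally cohesive, which 50 does not always), `blobs10` /
  `blobs20` (K=10/20, 50/cluster, 10-D, spacing 7σ — moderately
  overlapping, single-cell-like).
* `multiview_blobs` — one shared 3-cluster assignment, rendered per
  view by freshly drawn unit-variance centres in 500-dimensional
  feature space plus independent N(0, noise_sd) noise. The preset noise
  (5.2) is calibrated to the integration-matters regime: each view
  alone recovers K=3 in only about two-thirds of replicates while the
  fused two-view graph almost always does. The number of views (2) is a
  package choice; it is configurable.
* `nonconvex_shapes` — `spirals`: two interleaved Archimedean arms
  (r = 0.5 + 2t, φ = 3πt, the second arm rotated by π) sampled
  *deterministically* with even arc-length spacing, so the noiseless
  preset is a fixed test pattern; at n = 200 the default P = 3 kernel
  over-smooths across arms while tuning selects a more local P and
  separates them perfectly — the motivating case for kernel tuning.
  `worms`: two elongated interlocking crescents (2.5:1 aspect) with
  0.08 jitter at n = 300, the regime where the CNN term's suppression
  of shared-neighbour-poor cross-band links gives the density-aware
  kernel a clear advantage over the Zelnik-Manor kernel.

Problem sizes throughout the validation suite (N = 200–1000 for full
pipelines, N = 5000 for the FASP check with m = 900) are the package's
own choice of smallest sizes at which each regime is stable.

## Numerical conventions and degenerate inputs

* Kernel symmetry is enforced exactly (`max(A, Aᵀ)` against fp noise);
  the diagonal is set to exactly 1.
* Eigendecomposition requires symmetry within 1e−10 and fulfils
  `L·x = λx` within 1e−8 (tested); eigenvalues of the normalised
  operator lie in [−1, 1] within 1e−8.
* Row normalisation guarantees row sums of 1 within 1e−12; a zero row
  raises (cannot occur when the diagonal is retained).
* Ties: neighbour ranking, CV ranking and kNN retention all use stable
  sorts (ascending original index); eigengap and tuning ties resolve
  toward the smaller candidate.
* Labels are 1-based in every output; GMM component indices are
  otherwise arbitrary.
* Multi-view inputs are aligned to the first view by sample ID before
  any numeric work; non-shared IDs raise with the offending IDs named.

## Limitations

* The kernel is for continuous data only; binary (e.g. mutation)
  matrices need a different similarity.
* Views must share all samples — there is no missing-view imputation.
* Equal view weighting: a dominant noisy view degrades the fusion.
* The dip-based selection needs the informative eigenvectors to be
  genuinely multimodal; with maxK close to the true K the series is too
  short (K can be at most maxK − 1 on the dip path).
* FASP treats centroids as unweighted points; very uneven cluster sizes
  at aggressive compression can bias the centroid-stage graph.
* The full pipeline stores dense N×N matrices: beyond a few thousand
  samples use the FASP route.
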