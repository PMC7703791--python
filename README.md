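# spectrumclust

Density-aware spectral clustering for single- and multi-view omic data.

`spectrumclust` addresses a recurring problem in transcriptomics and
multi-omics: partitioning samples (patients, single cells) into subtypes
from one or several continuous feature-by-sample matrices — mRNA, miRNA,
protein or methylation panels over a shared sample set, or the
expression profiles of individual cells — while (i) choosing the number
of clusters *K* automatically, (ii) integrating multiple data views into
one shared structure, and (iii) handling both compact Gaussian-like
clusters and non-convex shapes. It is aimed at computational biologists
who want a fast, deterministic command-line/library tool rather than a
modelling framework.

## Method

**Similarity.** For samples *s<sub>i</sub>*, *s<sub>j</sub>* with
Euclidean distance *d(s<sub>i</sub>, s<sub>j</sub>)* the affinity is the
self-tuning, density-aware kernel

```
A_ij = exp( − d²(s_i, s_j) / (σ_i σ_j (CNN_ij + 1)) )
```

where *σ<sub>i</sub>* is the distance from *s<sub>i</sub>* to its *P*-th
nearest neighbour (local scale, default *P* = 3) and *CNN<sub>ij</sub>*
is the number of points shared by the two samples' *S*-nearest-neighbour
sets (default *S* = 7). Shared neighbourhoods inflate the similarity, so
connections inside dense regions are strengthened without any
per-dataset bandwidth tuning. Setting *CNN* ≡ 0 recovers the classic
Zelnik-Manor self-tuning kernel (available as `kernel="zelnik"`).

**Integration and diffusion.** Per-view kernels are summed with equal
weight, sparsified to each row's *Z* = 10 strongest links (plus the
diagonal), row-normalised, and smoothed by the diffusion recursion
*Q<sub>t</sub> = A Q<sub>t−1</sub> Aᵀ + I* for *iters* = 5 iterations —
the efficient equivalent of diffusion on the tensor-product graph of the
views. The result *A\** is symmetrised and normalised into
*L = D<sup>−1/2</sup> A\* D<sup>−1/2</sup>*.

**Number of clusters.** Two heuristics over the spectrum of *L*
(eigenvalues sorted descending):

* *eigengap*: K\* = argmax<sub>n=2..maxK</sub> (λ<sub>n</sub> −
  λ<sub>n+1</sub>);
* *multimodality gap*: each leading eigenvector is scored with the
  Hartigan–Hartigan dip statistic; the consecutive differences
  d<sub>j</sub> = z<sub>j+1</sub> − z<sub>j</sub> collapse sharply just
  past the true K, and the *last substantial drop* (a later drop
  replaces the stored one when it is *f* = 2-fold more negative, within
  a look-ahead window of c<sub>max</sub> = 7) picks K. This variant also
  recognises non-Gaussian structures and can tune *P* over 1..10 by
  maximising the gap (`tune=True` / `--tune`).

**Clustering.** The top-K eigenvectors are stacked, rows renormalised to
unit length, and a K-component full-covariance Gaussian mixture assigns
labels. For large *N* the FASP route compresses samples to *m* k-means
centroids (default 900) first, clusters the centroids, and propagates
labels back, so the spectral stage only ever touches *m × m* matrices.

## Worked example

Simulate five well-separated Gaussian clusters, cluster the matrix, and
score against the generating labels:

```bash
$ spectrum-clust simulate --preset blobs5 --seed 7 --out .
wrote blobs5.tsv
wrote blobs5_truth.tsv (K_true = 5)

$ spectrum-clust run --input blobs5.tsv --method eigengap --seed 7 --out blobs5_run
K = 5 (eigengap)
wrote blobs5_run_labels.tsv
wrote blobs5_run_diagnostics.tsv
wrote blobs5_run_config.yaml

$ spectrum-clust eval --labels blobs5_run_labels.tsv --truth blobs5_truth.tsv
NMI = 1.0000
ARI = 1.0000
```

`K = 5 (eigengap)` is the automatically selected number of clusters; NMI
and ARI of 1.0 mean the recovered partition matches the ground truth
exactly. The diagnostics file shows why K = 5 was chosen — the gap
between the fifth and sixth eigenvalues dwarfs every other candidate
(the leading five eigenvalues are all ≈ 1 because the diffused graph has
five tightly connected blocks):

```
candidate_k  eigengap
2            0.0
3            4.4e-16
4            3.3e-16
5            0.0848
6            0.0113
...
```

The same library calls are available in Python:

```python
from spectrumclust import preset, spectrum_cluster, ari

truth = preset("blobs5", seed=7)
result = spectrum_cluster(truth.X, method="eigengap", seed=7)
result.k                      # 5
ari(result.labels, truth.labels)  # 1.0
```

Multi-view runs pass several `--input` files (samples aligned by ID);
`--method dip [--tune]` switches to multimodality-gap selection;
`--fasp --centroids 900` enables the compression route.

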