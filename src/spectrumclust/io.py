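"""File I/O, feature filtering and partition-agreement metrics.

Matrix files are TSV (or CSV, by extension) with a header row of sample
ids and a first column of feature ids — the common layout of processed
omics tables.  A transpose flag accepts samples-in-rows files.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .types import ClusteringResult, ExpressionMatrix, InputError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "cv_filter",
    "nmi",
    "ari",
    "write_result",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a feature-by-sample matrix file.

    ``transpose=True`` for files with samples in rows.  Missing or
    non-numeric cells and duplicate identifiers raise with the offending
    coordinates named.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dupes += sorted(set(df.index[df.index.duplicated()]))
    if dupes:
        raise InputError(f"duplicate identifiers in {path.name}: {sorted(set(dupes))}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"missing/non-numeric cell in {path.name} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def write_matrix(X: ExpressionMatrix, path) -> None:
    path = Path(path)
    X.to_dataframe().to_csv(path, sep=_sep_for(path))


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, cluster) TSV/CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise InputError(f"{path.name}: expected columns sample_id, cluster")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def cv_filter(X: ExpressionMatrix, keep_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep the top fraction of features by coefficient of variation.

    CV = |sd/mean| per feature (descending, ties by feature order);
    zero-mean features get infinite CV — always kept — with a warning.
    """
    if not 0 < keep_fraction <= 1:
        raise InputError(f"keep_fraction={keep_fraction} outside (0, 1]")
    means = X.values.mean(axis=1)
    sds = X.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.abs(sds / means)
    zero_mean = means == 0
    if zero_mean.any():
        warnings.warn(
            f"{int(zero_mean.sum())} zero-mean feature(s): CV treated as infinite"
        )
        cv[zero_mean] = np.inf
    cv[np.isnan(cv)] = np.inf  # 0/0: zero-mean, zero-sd
    n_keep = math.ceil(keep_fraction * X.n_features)
    top = np.sort(np.argsort(-cv, kind="stable")[:n_keep])  # original feature order
    return ExpressionMatrix(
        X.values[top], list(X.sample_ids), [X.feature_ids[i] for i in top]
    )


def _aligned(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a, b = pd.Series(labels_a), pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise InputError("label sets cover different samples")
    b = b.reindex(a.index)
    return a.to_numpy(), b.to_numpy()


def nmi(labels_a, labels_b) -> float:
    """Normalised mutual information (arithmetic-mean normalisation)."""
    a, b = _aligned(labels_a, labels_b)
    if len(set(a)) < 2 or len(set(b)) < 2:
        warnings.warn("single-cluster partition: NMI defined as 0")
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index."""
    a, b = _aligned(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def write_result(
    result: ClusteringResult,
    prefix,
    config: dict | None = None,
    write_similarity: bool = False,
) -> list[Path]:
    """Write labels, K-selection diagnostics and (optionally) the fused
    similarity matrix plus a config snapshot under ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    labels_path = prefix.with_name(prefix.name + "_labels.tsv")
    result.labels.rename_axis("sample_id").to_frame("cluster").to_csv(
        labels_path, sep="\t"
    )
    written.append(labels_path)

    diag_path = prefix.with_name(prefix.name + "_diagnostics.tsv")
    result.k_selection.diagnostics_frame().to_csv(diag_path, sep="\t", index=False)
    written.append(diag_path)

    if write_similarity:
        sim_path = prefix.with_name(prefix.name + "_similarity.tsv")
        ids = result.fused_graph.sample_ids
        V = result.fused_graph.values
        sym = (V + V.T) / 2.0  # the symmetrised operator fed to the Laplacian
        pd.DataFrame(sym, index=ids, columns=ids).to_csv(
            sim_path, sep="\t", float_format="%.12g"
        )
        written.append(sim_path)

    if config is not None:
        import yaml

        cfg_path = prefix.with_name(prefix.name + "_config.yaml")
        cfg = dict(config)
        cfg["selected_k"] = int(result.k)
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        written.append(cfg_path)
    return written
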