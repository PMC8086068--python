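"""Hierarchical clustering of the mimQTL sign matrix (correlation distance,
average linkage) and value-space clustering for subgroup heatmaps
(Euclidean distance, average linkage, optional per-row scaling).

Cluster labels are size-ranked: the largest cluster gets the first alias
("A" for miRNAs, "1" for CpGs), and so on.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import OmicsMatrix
from .screen import MimQTLTable

log = logging.getLogger("mimqtl")

__all__ = [
    "ClusterAssignment",
    "correlation_distance",
    "hierarchical_cluster",
    "cut_tree_assign",
    "cluster_sign_matrix",
    "cluster_values_for_subgroups",
    "cluster_summaries",
]


@dataclass
class ClusterAssignment:
    """A flat clustering of one axis of the sign matrix.

    ``labels`` maps feature_id -> cluster alias; ``linkage`` is the scipy
    linkage matrix ((n-1) x 4 merge table).
    """

    axis: str  # "mirna" or "cpg"
    labels: pd.Series
    k: int
    linkage: np.ndarray

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def cluster_names(self) -> list[str]:
        return sorted(self.labels.unique())


def correlation_distance(rows: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise d(u, v) = 1 - Pearson(u, v) between matrix rows.

    Values lie in [0, 2]. Rows with zero variance have undefined correlation;
    they are assigned distance 1 to every other row (and 0 to themselves),
    which is logged. Note the correlation distance violates the triangle
    inequality in general — it is a dissimilarity, not a metric.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows to compute distances")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        log.warning("correlation_distance: %d constant row(s) set to distance 1",
                    int(constant.sum()))
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - corr
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(distance: np.ndarray, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering (UPGMA for ``average``) on a square
    symmetric distance matrix with zero diagonal."""
    D = np.asarray(distance, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    condensed = squareform(D, checks=False)
    return hierarchy.linkage(condensed, method=linkage)


def _aliases(axis: str, k: int) -> list[str]:
    if axis == "mirna":
        letters = list(string.ascii_uppercase)
        return letters[:k] if k <= 26 else [f"M{i+1}" for i in range(k)]
    return [str(i + 1) for i in range(k)]


def cut_tree_assign(Z: np.ndarray, ids, k: int, axis: str) -> ClusterAssignment:
    """Cut the tree into exactly k clusters (undoing the k-1 highest merges)
    and alias clusters by decreasing size."""
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} features")
    raw = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    sizes = pd.Series(raw).value_counts()
    # stable order: by decreasing size, ties by first appearance
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    aliases = _aliases(axis, k)
    mapping = {c: aliases[i] for i, c in enumerate(order)}
    labels = pd.Series([mapping[c] for c in raw], index=pd.Index(ids), name="cluster")
    return ClusterAssignment(axis, labels, k, Z)


def cluster_sign_matrix(sign: pd.DataFrame, k_mirna: int = 3,
                        k_cpg: int = 2) -> tuple[ClusterAssignment, ClusterAssignment]:
    """Cluster both axes of a CpG x miRNA sign matrix with correlation
    distance and average linkage."""
    d_cpg = correlation_distance(sign.to_numpy())
    d_mir = correlation_distance(sign.to_numpy().T)
    cpg_assign = cut_tree_assign(hierarchical_cluster(d_cpg), sign.index, k_cpg, "cpg")
    mir_assign = cut_tree_assign(hierarchical_cluster(d_mir), sign.columns, k_mirna, "mirna")
    log.info("cluster_sign_matrix: %d CpGs -> %d clusters, %d miRNAs -> %d clusters",
             len(sign.index), k_cpg, len(sign.columns), k_mirna)
    return mir_assign, cpg_assign


def cluster_values_for_subgroups(matrix: OmicsMatrix, scale_rows: bool = True
                                 ) -> dict:
    """Heatmap-style clustering of a value matrix: optional per-row
    z-scaling, Euclidean distance, average linkage on both axes. Returns
    linkage matrices and leaf orders for rows (features) and columns
    (samples). Zero-variance rows are left unscaled with a warning."""
    X = matrix.values.to_numpy(dtype=float).copy()
    if scale_rows:
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            log.warning("cluster_values_for_subgroups: %d zero-variance rows "
                        "left unscaled", int(flat.sum()))
        sd[sd == 0] = 1.0
        X = (X - mean) / sd
    row_Z = hierarchy.linkage(X, method="average", metric="euclidean")
    col_Z = hierarchy.linkage(X.T, method="average", metric="euclidean")
    return {
        "row_linkage": row_Z,
        "col_linkage": col_Z,
        "row_order": [matrix.feature_ids[i] for i in hierarchy.leaves_list(row_Z)],
        "col_order": [matrix.sample_ids[i] for i in hierarchy.leaves_list(col_Z)],
        "scaled": X,
    }


def cluster_summaries(table: MimQTLTable, mirna_assign: ClusterAssignment,
                      cpg_assign: ClusterAssignment) -> dict:
    """Accounting per miRNA cluster: mimQTL pair counts and shares, sign
    fractions, and per-feature association counts."""
    rec = table.records
    missing = set(rec["mirna_id"]) - set(mirna_assign.labels.index)
    missing |= set(rec["cpg_id"]) - set(cpg_assign.labels.index)
    if missing:
        raise ValueError(f"features not covered by cluster assignment: "
                         f"{sorted(missing)[:5]}")
    by_cluster = rec.groupby(rec["mirna_id"].map(mirna_assign.labels))
    total = len(rec)
    per_cluster = {}
    for name, grp in by_cluster:
        neg = int((grp["sign"] < 0).sum())
        per_cluster[name] = {
            "n_pairs": len(grp),
            "share": len(grp) / total,
            "n_mirnas": grp["mirna_id"].nunique(),
            "negative_fraction": neg / len(grp),
        }
    cpg_counts = {}
    for name in cpg_assign.cluster_names:
        cpg_counts[name] = int((cpg_assign.labels == name).sum())
    assoc_per_mirna = rec.groupby("mirna_id").size()
    assoc_per_cpg = rec.groupby("cpg_id").size()
    assert sum(c["n_pairs"] for c in per_cluster.values()) == total
    return {
        "total_pairs": total,
        "per_mirna_cluster": per_cluster,
        "cpg_cluster_sizes": cpg_counts,
        "associations_per_mirna": assoc_per_mirna,
        "associations_per_cpg": assoc_per_cpg,
        "median_cpgs_per_mirna": float(assoc_per_mirna.median()),
        "median_mirnas_per_cpg": float(assoc_per_cpg.median()),
    }
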