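"""Redundancy reduction by correlation clustering.

Features are clustered hierarchically on the distance 1 - |rho| (Spearman)
with average linkage, cutting the dendrogram where the mutual correlation
is 0.8; within each cluster, the feature with the highest mutual
information with the endpoint represents the cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

CLUSTER_RHO_THRESHOLD = 0.8
MI_BINS = 10


@dataclass
class ClusterAssignment:
    """Feature -> cluster id, per-feature MI (bits) and representative flag."""

    table: pd.DataFrame  # columns: cluster, mi, representative
    unclustered: list[str] = field(default_factory=list)

    @property
    def representatives(self) -> list[str]:
        return list(self.table.index[self.table["representative"]])


def spearman_abs_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """|Spearman rho| between all feature pairs (average ranks for ties,
    pairwise-complete observations); diagonal 1.

    Zero-variance features yield NaN rows/columns — they cannot be ranked
    against anything and are later passed through unclustered.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 patients for rank correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns
        rho = table.corr(method="spearman")
    out = rho.abs()
    np.fill_diagonal(out.values, 1.0)
    return out


def mutual_information_binary(
    values: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    n_bins: int = MI_BINS,
) -> float:
    """Plug-in mutual information (bits) between a feature and binary labels.

    The feature is discretized into equal-frequency bins; MI is computed
    from the bin x label contingency table. Rows with missing feature
    values are excluded.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    keep = np.isfinite(x)
    x, y = x[keep], y[keep]
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.digitize(x, edges)
    joint = np.zeros((bins.max() + 1, 2))
    for cls_idx, cls in enumerate(classes):
        counts = np.bincount(bins[y == cls], minlength=bins.max() + 1)
        joint[:, cls_idx] = counts
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.sum(p[nz] * np.log2((p / (px * py))[nz])))


def cluster_features(
    similarity: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    table: pd.DataFrame,
    threshold: float = CLUSTER_RHO_THRESHOLD,
    n_bins: int = MI_BINS,
) -> ClusterAssignment:
    """Average-linkage clustering of features at mutual |rho| >= threshold.

    The dendrogram over distance 1 - |rho| is cut at 1 - threshold.
    Features whose correlations are undefined (zero variance) bypass
    clustering and are reported in ``unclustered``. Determinism: features
    are processed in lexicographic order; MI ties break lexicographically.
    """
    names = sorted(similarity.columns)
    sim = similarity.loc[names, names]
    bad = [c for c in names if sim[c].drop(c).isna().all()]
    if bad:
        warnings.warn(f"{len(bad)} zero-variance features passed through unclustered")
    good = [c for c in names if c not in bad]

    mi = {c: mutual_information_binary(table[c], labels, n_bins) for c in good}
    rows = {}
    if len(good) == 1:
        rows[good[0]] = (1, mi[good[0]], True)
    elif good:
        dist = 1.0 - sim.loc[good, good].to_numpy()
        dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        cluster_ids = fcluster(z, t=1.0 - threshold, criterion="distance")
        for cid in np.unique(cluster_ids):
            members = [good[i] for i in np.where(cluster_ids == cid)[0]]
            rep = max(members, key=lambda c: (mi[c], c))  # ties -> later name
            # lexicographic tie-break, deterministic: among equal MI pick smallest
            best_mi = mi[rep]
            rep = sorted(c for c in members if mi[c] == best_mi)[0]
            for c in members:
                rows[c] = (int(cid), mi[c], c == rep)
    tab = pd.DataFrame.from_dict(
        rows, orient="index", columns=["cluster", "mi", "representative"]
    ).sort_index()
    return ClusterAssignment(table=tab, unclustered=bad)


def reduce_features(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    threshold: float = CLUSTER_RHO_THRESHOLD,
) -> tuple[pd.DataFrame, ClusterAssignment]:
    """Cluster features and keep one representative per cluster.

    Unclustered (zero-variance) features are excluded from the reduced
    table: they carry no information about the endpoint.
    """
    sim = spearman_abs_matrix(table)
    assignment = cluster_features(sim, labels, table, threshold)
    return table[assignment.representatives], assignment


__all__ = [
    "ClusterAssignment", "CLUSTER_RHO_THRESHOLD", "MI_BINS",
    "spearman_abs_matrix", "mutual_information_binary", "cluster_features",
    "reduce_features",
]
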