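"""Unsupervised hierarchical clustering with desktop-microarray conventions.

Distances follow the conventions of the classic microarray clustering
tools: correlation metrics give distance 1 - r, where the uncentered
variant uses raw (non-mean-subtracted) cross-products; linkage is average
or complete.  Items are sorted by ID before clustering so results are
independent of input order, with ties resolved deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = ["ClusterTree", "hierarchical_cluster"]

METRICS = ("uncentered_correlation", "pearson", "euclidean")
LINKAGES = ("average", "complete")


@dataclass
class ClusterTree:
    items: list[str]  # leaf IDs in clustering input order (sorted by ID)
    merges: list[tuple[int, int, float]]  # (node_i, node_j, height), scipy numbering
    linkage_matrix: np.ndarray
    metric: str
    linkage: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k groups (flat cluster labels 1..k)."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.items, (int(v) for v in labels)))

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def recurse(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.items[node.id]}:{length:g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        left = recurse(root.left, root.dist)
        right = recurse(root.right, root.dist)
        return f"({left},{right});"

    def merges_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_i", "node_j", "height"])


def _distance_matrix(data: np.ndarray, metric: str, ids: list[str]) -> np.ndarray:
    if metric == "euclidean":
        diff = data[:, None, :] - data[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "pearson":
        sd = data.std(axis=1)
        if np.any(sd == 0):
            bad = ids[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"zero-variance item under pearson: {bad!r}")
        r = np.corrcoef(data)
        return 1.0 - r
    if metric == "uncentered_correlation":
        norms = np.sqrt((data**2).sum(axis=1))
        if np.any(norms == 0):
            bad = ids[int(np.flatnonzero(norms == 0)[0])]
            raise ValueError(f"zero-norm item under uncentered correlation: {bad!r}")
        r = (data @ data.T) / np.outer(norms, norms)
        return 1.0 - r
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def hierarchical_cluster(
    m: ExpressionMatrix,
    axis: str = "samples",
    metric: str = "uncentered_correlation",
    linkage: str = "average",
) -> ClusterTree:
    """Cluster samples or genes; returns the merge tree.

    Median-center gene rows upstream when reproducing heatmap-style sample
    clustering on relative expression.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if axis == "samples":
        ids = sorted(str(s) for s in m.sample_ids)
        data = m.values[ids].to_numpy(dtype=float).T
    elif axis == "genes":
        ids = sorted(str(g) for g in m.gene_ids)
        data = m.values.loc[ids].to_numpy(dtype=float)
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if len(ids) < 2:
        raise ValueError("need at least 2 items to cluster")
    dist = _distance_matrix(data, metric, ids)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)  # guard tiny negative rounding
    dist = (dist + dist.T) / 2.0
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return ClusterTree(items=ids, merges=merges, linkage_matrix=z, metric=metric, linkage=linkage)
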