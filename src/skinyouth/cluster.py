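"""Hierarchical clustering for heatmap ordering.

Agglomerative clustering with correlation distance (1 - Pearson r) and
average linkage, the usual choice for expression heatmaps.  In the
youthfulness heatmap only genes are clustered; samples are ordered by
their ``r_delta`` phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


class UndefinedDistanceError(ValueError):
    """Correlation distance is undefined for a constant item."""


@dataclass
class Dendrogram:
    """Agglomerative merge tree over items.

    ``merges`` is the scipy linkage matrix (each row: left, right,
    height, size); ``heights`` the per-merge heights (non-decreasing for
    average linkage on a metric-ish distance); ``leaf_order`` the leaf
    permutation used for display.
    """

    items: list
    merges: np.ndarray
    leaf_order: list

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Nested-parenthesis (Newick) rendering with branch lengths."""
        tree = hierarchy.to_tree(self.merges)

        def render(node) -> str:
            if node.is_leaf():
                return str(self.items[node.id])
            left, right = node.left, node.right
            return (
                f"({render(left)}:{node.dist - left.dist:.6g},"
                f"{render(right)}:{node.dist - right.dist:.6g})"
            )

        return render(tree) + ";"


def hierarchical_cluster(
    values: pd.DataFrame, axis: str = "genes", metric: str = "1-pearson",
    linkage: str = "average"
) -> Dendrogram:
    """Cluster rows (``axis='genes'``) or columns (``axis='samples'``).

    Distance is 1 - Pearson correlation between item profiles (or any
    scipy pdist metric name); linkage defaults to average.  Constant
    items make the correlation distance undefined and raise.
    """
    X = values.to_numpy(dtype=float) if axis == "genes" else values.to_numpy(dtype=float).T
    items = list(values.index if axis == "genes" else values.columns)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if metric == "1-pearson":
        sd = X.std(axis=1)
        if (sd == 0).any():
            bad = [items[i] for i in np.where(sd == 0)[0]]
            raise UndefinedDistanceError(
                f"constant item(s) under correlation metric: {bad[:5]}"
            )
        dist = 1.0 - np.corrcoef(X)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(X, metric=metric)
    merges = hierarchy.linkage(condensed, method=linkage)
    leaf_order = [items[i] for i in hierarchy.leaves_list(merges)]
    return Dendrogram(items=items, merges=merges, leaf_order=leaf_order)
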