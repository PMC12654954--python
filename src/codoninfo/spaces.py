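"""Multivariate-space analysis: distances, dendrograms and outlier profiles.

Species (or groups, or measure columns) are points in a feature space —
the 8- or 54-dimensional entropy space, the 64-dimensional relative
codon frequency (RCF) space, or the space spanned by sI columns.
Relatedness is summarised by Euclidean distances and complete-linkage
dendrograms; atypical species are profiled by their distance to the
componentwise median vector of each space.

The agglomeration here is written in-house rather than delegated to
scipy so that ties between merge candidates are broken deterministically
(by the lexicographically smallest sorted leaf-label lists), making
dendrograms independent of input row order.  Results agree with scipy's
``linkage(..., 'complete')`` whenever no ties occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .comparative import pearson

__all__ = [
    "group_median_matrix",
    "euclidean_distances",
    "Dendrogram",
    "complete_linkage",
    "measure_column_dendrogram",
    "distance_to_median_profile",
    "OutlierReport",
]


def group_median_matrix(features: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Componentwise median vector of each group; one row per group key."""
    g = groups.reindex(features.index)
    if g.isna().any():
        raise ValueError("every row needs a group assignment")
    out = features.groupby(g).median()
    out.index.name = "group"
    return out.sort_index()


def euclidean_distances(features: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric Euclidean distance matrix between rows."""
    if len(features) < 2:
        raise ValueError("need at least 2 rows to compute distances")
    from scipy.spatial.distance import pdist, squareform

    x = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=features.index, columns=features.index)


@dataclass
class _Node:
    """Binary merge-tree node; leaves carry a label, internal nodes a height."""

    height: float
    label: str | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over labeled points.

    ``merges`` records, in order, (members of the new cluster, height);
    heights are non-decreasing (complete linkage is monotone).
    """

    root: _Node
    merges: list[tuple[tuple[str, ...], float]]

    @property
    def leaves(self) -> list[str]:
        return self.root.leaves()

    @property
    def heights(self) -> list[float]:
        return [h for _, h in self.merges]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""

        def render(node: _Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.12g}"
            inner = ",".join(
                render(ch, node.height) for ch in (node.left, node.right)
            )
            return f"({inner}):{bl:.12g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(
            render(ch, self.root.height) for ch in (self.root.left, self.root.right)
        )
        return f"({inner}):0;"


def complete_linkage(distances: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with the complete-linkage criterion.

    Repeatedly merges the two clusters whose *maximum* pairwise member
    distance is smallest; that maximum becomes the merge height.  Among
    equal-distance candidates the pair whose combined sorted leaf-label
    list is lexicographically smallest is merged, so the result does not
    depend on input row order.
    """
    labels = [str(l) for l in distances.index]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    d = distances.to_numpy(dtype=float).copy()
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains NaN or inf")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")

    nodes: dict[int, _Node] = {
        i: _Node(height=0.0, label=labels[i]) for i in range(n)
    }
    members: dict[int, list[str]] = {i: [labels[i]] for i in range(n)}
    active = list(range(n))
    np.fill_diagonal(d, np.inf)
    merges: list[tuple[tuple[str, ...], float]] = []

    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        dmin = sub.min()
        # deterministic tie-break over all candidate pairs at dmin
        best_key = None
        best_pair = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if d[i, j] <= dmin:
                    key = sorted(members[i] + members[j])
                    if best_key is None or key < best_key:
                        best_key, best_pair = key, (i, j)
        i, j = best_pair
        h = float(d[i, j])
        # left/right ordered so the smaller leading leaf label comes first
        a, b = nodes[i], nodes[j]
        if sorted(b.leaves()) < sorted(a.leaves()):
            a, b = b, a
        new = _Node(height=h, left=a, right=b)
        nodes[i] = new
        members[i] = best_key
        merges.append((tuple(best_key), h))
        # Lance-Williams update for complete linkage: max of the two rows
        d[i, :] = np.maximum(d[i, :], d[j, :])
        d[:, i] = d[i, :]
        d[i, i] = np.inf
        active.remove(j)

    return Dendrogram(root=nodes[active[0]], merges=merges)


def measure_column_dendrogram(
    measures: pd.DataFrame,
    columns: Sequence[str] | None = None,
    label_map: dict[str, str] | None = None,
) -> Dendrogram:
    """Dendrogram over measure *columns*, species values as features.

    ``label_map`` renames columns for display, e.g. ``sI(aa;T)`` ->
    ``aa.T``.
    """
    cols = list(columns) if columns is not None else list(measures.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 measure columns")
    sub = measures[cols].T
    if label_map:
        sub.index = [label_map.get(c, c) for c in sub.index]
    return complete_linkage(euclidean_distances(sub))


@dataclass
class OutlierReport:
    """Per-species distances to the global median vectors of two spaces."""

    distances: pd.DataFrame  # columns: group, dist_H, dist_RCF, rank_H, rank_RCF
    correlation: float  # Pearson r between the two distance columns
    group_maxima: pd.DataFrame  # per group: the species farthest out in H space


def distance_to_median_profile(
    h_features: pd.DataFrame,
    rcf_features: pd.DataFrame,
    groups: pd.Series,
) -> OutlierReport:
    """Distances of every species to the pooled median point of each space.

    The median vector is the componentwise median over all species.
    Ranks are 1 = farthest.  ``group_maxima`` lists, per group, the
    species with the largest H-space distance (the group's outlier).
    """
    if not h_features.index.equals(rcf_features.index):
        raise ValueError("the two spaces must cover the same species in the same order")
    if len(h_features) < 2:
        raise ValueError("need at least 2 species")
    g = groups.reindex(h_features.index)
    if g.isna().any():
        raise ValueError("every species needs a group assignment")

    def dists(features: pd.DataFrame) -> np.ndarray:
        x = features.to_numpy(dtype=float)
        med = np.median(x, axis=0)
        return np.sqrt(((x - med) ** 2).sum(axis=1))

    dh = dists(h_features)
    dr = dists(rcf_features)
    df = pd.DataFrame(
        {
            "group": g.to_numpy(),
            "dist_H": dh,
            "dist_RCF": dr,
        },
        index=h_features.index,
    )
    df["rank_H"] = df["dist_H"].rank(ascending=False, method="first").astype(int)
    df["rank_RCF"] = df["dist_RCF"].rank(ascending=False, method="first").astype(int)
    r, _ = pearson(dh, dr)
    idx = df.groupby("group")["dist_H"].idxmax()
    gmax = df.loc[idx].sort_values("dist_H", ascending=False)
    gmax = gmax.reset_index().rename(columns={"index": "label"})
    return OutlierReport(distances=df, correlation=r, group_maxima=gmax)
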