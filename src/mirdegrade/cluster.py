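"""Hierarchical clustering (Euclidean distance, complete linkage) with a
fixed-k tree cut and cluster-vs-miRBase-version summaries.

The agglomeration is implemented directly (rather than delegated) so that
tie-breaking is fully specified: when several pairs attain the minimal
complete-linkage distance, the pair with the smallest (row, column) position
is merged.  This makes dendrograms byte-reproducible across platforms, which
matters because downstream cluster labels feed the version-bias summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .model import ExpressionMatrix, MiRBaseAnnotation, ValidationError

__all__ = [
    "euclidean_distances",
    "Dendrogram",
    "ClusterAssignment",
    "complete_linkage",
    "cut_tree",
    "cluster_version_summary",
]


def euclidean_distances(m: ExpressionMatrix, axis: str = "mirnas") -> pd.DataFrame:
    """Pairwise Euclidean distances between miRNAs (rows) or samples (columns)."""
    if m.state != "normalized":
        raise ValidationError("euclidean_distances expects a normalized matrix")
    X = m.values.to_numpy()
    if not np.isfinite(X).all():
        coords = np.argwhere(~np.isfinite(X))[:5]
        locs = [
            (m.mirna_ids[i], m.sample_ids[j]) for i, j in coords
        ]
        raise ValidationError(f"missing values at {locs}")
    if axis == "mirnas":
        ids = m.mirna_ids
    elif axis == "samples":
        ids = m.sample_ids
        X = X.T
    else:
        raise ValidationError("axis must be 'mirnas' or 'samples'")
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[t] = (i, j, height)`` joins nodes i < j at the given height;
    leaves are numbered 0..n−1 in input order and the node created by merge t
    is numbered n + t.  Complete linkage guarantees non-decreasing heights.
    """

    ids: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValidationError(
                f"{self.n_leaves} leaves require {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    def members(self) -> dict[int, list[int]]:
        """Leaf sets of every node (leaves and internal)."""
        out = {i: [i] for i in range(self.n_leaves)}
        for t, (i, j, _) in enumerate(self.merges):
            out[self.n_leaves + t] = out[i] + out[j]
        return out

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the tree drawing."""
        if self.n_leaves == 1:
            return [0]
        children: dict[int, tuple[int, int]] = {}
        for t, (i, j, _) in enumerate(self.merges):
            children[self.n_leaves + t] = (i, j)

        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                i, j = children[node]
                stack.extend([j, i])
        return order

    def to_linkage_matrix(self) -> np.ndarray:
        """Scipy-style (n−1) × 4 linkage matrix (for plotting/interop)."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        Z = np.zeros((len(self.merges), 4))
        for t, (i, j, h) in enumerate(self.merges):
            size = sizes[i] + sizes[j]
            sizes[self.n_leaves + t] = size
            Z[t] = [i, j, h, size]
        return Z

    def to_newick(self) -> str:
        children: dict[int, tuple[int, int]] = {}
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for t, (i, j, h) in enumerate(self.merges):
            children[self.n_leaves + t] = (i, j)
            heights[self.n_leaves + t] = h

        def render(node: int) -> str:
            if node < self.n_leaves:
                label = str(self.ids[node]).replace(" ", "_").replace(",", "_")
                return label
            i, j = children[node]
            bi = heights[node] - heights[i]
            bj = heights[node] - heights[j]
            return f"({render(i)}:{bi:.6g},{render(j)}:{bj:.6g})"

        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return render(root) + ";"


@dataclass
class ClusterAssignment:
    """item id → cluster label; labels are contiguous 1..k, assigned by
    decreasing cluster size (ties by the lexicographically smallest member)."""

    labels: dict[str, int]

    @property
    def k(self) -> int:
        return max(self.labels.values()) if self.labels else 0

    def members_of(self, label: int) -> list[str]:
        return [i for i, lab in self.labels.items() if lab == label]

    def __post_init__(self) -> None:
        labs = set(self.labels.values())
        if labs and labs != set(range(1, len(labs) + 1)):
            raise ValidationError("cluster labels must be contiguous from 1")


def complete_linkage(d: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with max-linkage inter-cluster distance.

    Ties on the minimal distance are broken by the smallest (row, column)
    index pair in the current active ordering, so the result is deterministic.
    """
    D = np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 items to cluster")
    ids = [str(c) for c in d.columns] if isinstance(d, pd.DataFrame) else [
        str(i) for i in range(n)
    ]

    W = D.copy()
    np.fill_diagonal(W, np.inf)
    node = list(range(n))  # node id currently held by each active slot
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    for t in range(n - 1):
        sub = W.copy()
        sub[~active, :] = np.inf
        sub[:, ~active] = np.inf
        # upper triangle only: (i, j) with i < j, smallest pair wins ties
        iu = np.triu_indices(n, k=1)
        flat = sub[iu]
        pos = int(np.argmin(flat))
        i, j = int(iu[0][pos]), int(iu[1][pos])
        h = float(sub[i, j])
        a, b = sorted((node[i], node[j]))
        merges.append((a, b, h))
        # slot i becomes the merged cluster; complete linkage = max
        newrow = np.maximum(W[i], W[j])
        W[i, :] = newrow
        W[:, i] = newrow
        W[i, i] = np.inf
        active[j] = False
        node[i] = n + t
    return Dendrogram(ids, merges)


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into exactly *k* clusters (undo the k−1 last merges)."""
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range [1, {n}]")
    live: dict[int, set] = {i: {i} for i in range(n)}
    for t in range(n - k):
        i, j, _ = dend.merges[t]
        live[n + t] = live.pop(i) | live.pop(j)
    groups = [sorted(g, key=lambda x: str(dend.ids[x])) for g in live.values()]
    groups.sort(key=lambda g: (-len(g), str(dend.ids[g[0]])))
    labels: dict[str, int] = {}
    for lab, g in enumerate(groups, start=1):
        for leaf in g:
            labels[dend.ids[leaf]] = lab
    return ClusterAssignment(labels)


def cluster_version_summary(
    assign: ClusterAssignment,
    annotation: Sequence[MiRBaseAnnotation],
) -> pd.DataFrame:
    """Per-cluster miRBase first-version summary (size, quartiles) plus a
    global Kruskal-Wallis statistic of version across clusters.

    Returns a DataFrame indexed by cluster label with columns
    ``size, q1, median, q3``; the Kruskal-Wallis H and p are attached as
    ``df.attrs["kruskal_h"]`` / ``df.attrs["kruskal_p"]`` (NaN when fewer
    than two clusters).
    """
    ann = {a.mirna_id: a for a in annotation}
    missing = [i for i in assign.labels if i not in ann]
    if missing:
        raise ValidationError(f"missing annotation for {missing[:5]}")
    rows = []
    per_cluster: list[list[int]] = []
    for lab in range(1, assign.k + 1):
        versions = [ann[i].first_version for i in assign.members_of(lab)]
        per_cluster.append(versions)
        rows.append(
            {
                "cluster": lab,
                "size": len(versions),
                "q1": float(np.percentile(versions, 25)),
                "median": float(np.median(versions)),
                "q3": float(np.percentile(versions, 75)),
            }
        )
    df = pd.DataFrame(rows).set_index("cluster")
    groups = [g for g in per_cluster if len(g) > 0]
    if len(groups) >= 2 and len(set(v for g in groups for v in g)) > 1:
        h, p = sps.kruskal(*groups)
        df.attrs["kruskal_h"] = float(h)
        df.attrs["kruskal_p"] = float(p)
    else:
        df.attrs["kruskal_h"] = float("nan")
        df.attrs["kruskal_p"] = float("nan")
    return df
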