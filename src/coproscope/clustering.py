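"""Hierarchical clustering of coprolite pollen assemblages.

Defaults follow the historical conventions of early gene-expression
clustering software: similarity is the uncentered Pearson correlation of
percentage vectors, distance = 1 - similarity, agglomeration is average
linkage.  Merging is deterministic: when several pairs tie at the minimum
distance the pair with the lowest (i, j) indices merges first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRICS = ("uncentered_pearson", "pearson", "euclidean")
LINKAGES = ("average", "single", "complete")


@dataclass
class AssemblageTree:
    """Merge history of an agglomerative clustering.

    ``merges`` rows are (left, right, height, size) in scipy linkage
    convention: leaves are 0..n-1, the cluster formed by merge k gets id
    n + k.  Heights are cophenetic distances at which clusters fused.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 4)
    metric: str
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, threshold: float) -> list[set[str]]:
        """Flat clusters: members connected by merges at height <= threshold."""
        n = self.n_leaves
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.merges):
            if h <= threshold:
                merged = members.pop(int(a)) | members.pop(int(b))
                members[n + k] = merged
            else:
                members[n + k] = set()  # placeholder so later merges can refer
        # clusters whose parent merge exceeded the threshold stay separate
        out = [c for c in members.values() if c]
        return [set(self.labels[i] for i in c) for c in sorted(out, key=min)]

    def to_newick(self) -> str:
        """Ultrametric Newick string with heights as node depths."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _s) in enumerate(self.merges):
            a, b = int(a), int(b)
            bl_a = h - height[a]
            bl_b = h - height[b]
            node[n + k] = f"({node[a]}:{bl_a:.6g},{node[b]}:{bl_b:.6g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";" if len(self.merges) else node[0] + ";"


def assemblage_distance(
    percent_matrix: pd.DataFrame, metric: str = "uncentered_pearson"
) -> pd.DataFrame:
    """Symmetric distance matrix between coprolite percentage vectors."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(percent_matrix) < 2:
        raise ValueError("need at least 2 coprolites")
    X = percent_matrix.to_numpy(dtype=float)
    if metric == "uncentered_pearson":
        norms = np.sqrt((X**2).sum(axis=1))
        if (norms == 0).any():
            raise ValueError("zero vector: uncentered correlation undefined")
        sim = (X @ X.T) / np.outer(norms, norms)
        dist = 1.0 - sim
    elif metric == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt((Xc**2).sum(axis=1))
        if (norms == 0).any():
            raise ValueError("zero-variance vector: centered correlation undefined")
        sim = (Xc @ Xc.T) / np.outer(norms, norms)
        dist = 1.0 - sim
    else:
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    ids = list(percent_matrix.index)
    return pd.DataFrame(dist, index=ids, columns=ids)


def hierarchical_cluster(
    distances: pd.DataFrame, linkage: str = "average"
) -> AssemblageTree:
    """Deterministic agglomerative clustering of a distance matrix.

    A direct quadratic agglomeration (n here is tens of coprolites, not
    thousands): at every step scan all active cluster pairs, merge the
    minimum-distance pair, tie-break on lowest indices, and update
    inter-cluster distances under the chosen linkage.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = distances.to_numpy(dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    labels = list(map(str, distances.index))
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    # active clusters: id -> (current matrix row, size)
    dist: dict[tuple[int, int], float] = {}
    active: dict[int, int] = {i: 1 for i in range(n)}  # id -> size
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    merges = np.zeros((n - 1, 4))
    next_id = n
    for k in range(n - 1):
        best = None
        ids = sorted(active)
        for ii, a in enumerate(ids):
            for b in ids[ii + 1:]:
                d = get(a, b)
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        sa, sb = active[a], active[b]
        new = next_id
        next_id += 1
        for c in ids:
            if c in (a, b):
                continue
            if linkage == "average":
                dnew = (sa * get(a, c) + sb * get(b, c)) / (sa + sb)
            elif linkage == "single":
                dnew = min(get(a, c), get(b, c))
            else:
                dnew = max(get(a, c), get(b, c))
            dist[(min(c, new), max(c, new))] = dnew
        del active[a], active[b]
        active[new] = sa + sb
        merges[k] = (a, b, d, sa + sb)
    return AssemblageTree(labels=labels, merges=merges,
                          metric="precomputed", linkage=linkage)


def similar_groups(tree: AssemblageTree, threshold: float = 0.1) -> list[set[str]]:
    """Groups of >=2 coprolites fused at or below the distance threshold."""
    return [g for g in tree.cut(threshold) if len(g) >= 2]


def group_assignments(
    tree: AssemblageTree, threshold: float = 0.1
) -> dict[str, str]:
    """Coprolite -> group label map; singletons get their own label.

    Group labels are ``G1, G2, ...`` in order of smallest member ID, so the
    labelling is invariant to input row order.
    """
    groups = tree.cut(threshold)
    out: dict[str, str] = {}
    for i, grp in enumerate(sorted(groups, key=lambda g: sorted(g)[0]), start=1):
        for member in sorted(grp):
            out[member] = f"G{i}"
    return out


def write_groups(assignments: dict[str, str], path: str) -> None:
    df = pd.DataFrame(
        sorted(assignments.items()), columns=["coprolite", "group"]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
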