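"""Sample dendrograms and Baker's Gamma Index across rarity thresholds.

The robustness question: does trimming ever-rarer OTUs out of the rare
biosphere change how the samples cluster?  Each rarity threshold yields a
rare-subset abundance table, a Bray-Curtis matrix and a dendrogram; pairs
of dendrograms are then compared with the Baker's Gamma Index (BGI) — the
Goodman-Kruskal gamma rank correlation between the cophenetic merge levels
of the two trees.  BGI 1 is perfect agreement, -1 perfect inversion, and
values near 0 mean the trees are unrelated.

Cophenetic comparison uses merge-step indices (the step at which a leaf
pair first shares a cluster), not raw merge heights, so the index is
invariant under monotone transforms of the linkage heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from raretaxa.betapart import bray_curtis

LINKAGES = ("average", "complete", "single", "ward")

__all__ = [
    "Dendrogram",
    "DendroComparison",
    "cluster_samples",
    "bakers_gamma",
    "gradient_bgi",
]


@dataclass
class Dendrogram:
    """A hierarchical clustering of labelled leaves.

    ``linkage_matrix`` is in scipy format: n-1 rows of
    (cluster_a, cluster_b, height, size).  Leaves are stored sorted
    lexicographically, which together with scipy's deterministic index-order
    merging makes clustering reproducible under input reordering.
    """

    leaves: tuple[str, ...]
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows of 4")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cophenetic_levels(self) -> pd.DataFrame:
        """Leaf x leaf matrix of merge-step indices (1 = first merge)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        lev = np.zeros((n, n), dtype=int)
        for step, (a, b, _h, _cnt) in enumerate(self.linkage_matrix, start=1):
            ma = members.pop(int(a))
            mb = members.pop(int(b))
            for i in ma:
                for j in mb:
                    lev[i, j] = lev[j, i] = step
            members[n - 1 + step] = ma + mb
        return pd.DataFrame(lev, index=list(self.leaves), columns=list(self.leaves))

    def to_newick(self) -> str:
        """Newick string with merge heights converted to branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            inner = ",".join(walk(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def cluster_samples(
    dist: pd.DataFrame | np.ndarray,
    linkage: str = "average",
    labels: list[str] | None = None,
) -> Dendrogram:
    """Agglomeratively cluster samples from a square distance matrix.

    The matrix must be symmetric with a zero diagonal and no negative
    entries, over at least 3 samples.  Default linkage is average (UPGMA);
    complete, single and ward are accepted.  Leaves are sorted
    lexicographically before clustering so the result does not depend on
    input column order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage: {linkage!r}")
    if isinstance(dist, pd.DataFrame):
        labels = [str(c) for c in dist.columns]
        mat = dist.to_numpy(dtype=float)
    else:
        mat = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"S{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if mat.shape != (n, n) or n < 3:
        raise ValueError("need a square distance matrix over >= 3 samples")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(mat) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(mat < 0):
        raise ValueError("distances must be non-negative")
    order = np.argsort(np.asarray(labels, dtype=object))
    leaves = tuple(labels[i] for i in order)
    mat = mat[np.ix_(order, order)]
    with warnings.catch_warnings():
        # ward on a non-Euclidean dissimilarity is permitted but noisy
        warnings.simplefilter("ignore")
        z = hierarchy.linkage(squareform(mat, checks=False), method=linkage)
    return Dendrogram(leaves=leaves, linkage_matrix=z)


def _level_vector(d: Dendrogram, pair_order: list[tuple[str, str]]) -> np.ndarray:
    lev = d.cophenetic_levels()
    return np.array([lev.at[a, b] for a, b in pair_order], dtype=float)


def bakers_gamma(d1: Dendrogram, d2: Dendrogram) -> float:
    """Baker's Gamma Index between two dendrograms on the same leaves.

    Goodman-Kruskal gamma ``(Nc - Nd) / (Nc + Nd)`` over all unordered
    pairs of leaf-pairs, comparing the two cophenetic merge-level vectors;
    ties in either vector contribute to neither Nc nor Nd.  Returns NaN
    (with a warning) in the degenerate all-ties case Nc + Nd = 0.
    Symmetric in its arguments and invariant under leaf relabeling order.
    """
    if set(d1.leaves) != set(d2.leaves):
        raise ValueError("dendrograms have different leaf sets")
    leaves = sorted(d1.leaves)
    pair_order = [
        (leaves[i], leaves[j])
        for i in range(len(leaves))
        for j in range(i + 1, len(leaves))
    ]
    a = _level_vector(d1, pair_order)
    b = _level_vector(d2, pair_order)
    sa = np.sign(a[:, None] - a[None, :])
    sb = np.sign(b[:, None] - b[None, :])
    prod = np.triu(sa * sb, k=1)
    nc = int((prod == 1).sum())
    nd = int((prod == -1).sum())
    if nc + nd == 0:
        warnings.warn("Baker's gamma undefined: all pair comparisons tied")
        return float("nan")
    return (nc - nd) / (nc + nd)


@dataclass
class DendroComparison:
    """Pairwise BGI matrix across the rarity-threshold gradient.

    ``bgi`` is symmetric with unit diagonal, indexed by threshold.
    ``excluded`` lists thresholds whose rare subset produced no usable
    abundance signal (empty or all-zero table) and were skipped.
    """

    thresholds: list[float]
    bgi: pd.DataFrame
    dendrograms: dict[float, Dendrogram] = field(default_factory=dict)
    excluded: list[float] = field(default_factory=list)


def gradient_bgi(
    X: pd.DataFrame,
    subsets: list[tuple[float, frozenset[str]]],
    linkage: str = "average",
) -> DendroComparison:
    """Cluster each rare-subset table and fill the pairwise BGI matrix.

    For each (threshold, OTU set): restrict X to the subset's rows, compute
    Bray-Curtis between samples on that slice, cluster, then compare every
    pair of threshold dendrograms with :func:`bakers_gamma`.
    """
    dendros: dict[float, Dendrogram] = {}
    excluded: list[float] = []
    for t, ids in subsets:
        sub = X.loc[sorted(ids)] if ids else X.iloc[0:0]
        if sub.shape[0] == 0 or not (sub.to_numpy() > 0).any():
            excluded.append(t)
            continue
        dendros[t] = cluster_samples(bray_curtis(sub), linkage=linkage)
    kept = list(dendros)
    bgi = pd.DataFrame(np.eye(len(kept)), index=kept, columns=kept)
    for i, t1 in enumerate(kept):
        for t2 in kept[i + 1 :]:
            g = bakers_gamma(dendros[t1], dendros[t2])
            bgi.at[t1, t2] = bgi.at[t2, t1] = g
    return DendroComparison(
        thresholds=[t for t, _ in subsets],
        bgi=bgi,
        dendrograms=dendros,
        excluded=excluded,
    )
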