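"""Hierarchical clustering of traits and entropy-based cluster evaluation.

A similarity matrix is turned into a dissimilarity (d = 1 - s for indices
bounded in [0, 1]; Pearson is shifted via d = (1 - s)/2; unbounded indices
are first rescaled by their largest off-diagonal value), clustered
agglomeratively, and cut into K clusters.  Cluster heterogeneity against a
predefined trait categorisation is scored with Gini-Simpson (1 - sum P_j^2)
or Shannon-Wiener (-sum P_j ln P_j) entropy; the per-tree summaries are

    E_K  = (1/K) sum_i E_i                (mean cluster entropy)
    E'_K = (1/K) sum_i E_i / N_i          (weighted: per cluster per trait)

where N_i is the size of cluster i.  E'_K cancels the bias of large clusters
towards high entropy.  Traits carrying two categories contribute half a
count to each, keeping sum_j P_j = 1.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "ClusterTree",
    "HeterogeneityProfile",
    "filter_clusterable_traits",
    "similarity_to_distance",
    "build_tree",
    "cut_tree",
    "cluster_entropy",
    "heterogeneity_curve",
]


@dataclass
class ClusterTree:
    """A trait dendrogram: scipy linkage matrix plus leaf labels."""

    leaf_labels: list[str]
    linkage_matrix: np.ndarray
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_newick(self) -> str:
        """Newick string with merge heights encoded as branch lengths."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        parts = {i: self.leaf_labels[i] for i in range(n)}
        for step, (a, b, h, _size) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            node = n + step
            parts[node] = f"({parts[a]}:{la:.6g},{parts[b]}:{lb:.6g})"
            heights[node] = h
        return parts[2 * n - 2] + ";"


@dataclass
class HeterogeneityProfile:
    """Entropy summary of one K-cluster cut."""

    K: int
    per_cluster: list[tuple[int, float]]  # (N_i, E_i)
    E_K: float
    E_K_weighted: float
    entropy_kind: str


def filter_clusterable_traits(pair_results, alpha: float = 0.05) -> set[str]:
    """Traits with at least one Bonferroni-significant pairwise overlap."""
    out: set[str] = set()
    for r in pair_results:
        if r.p_bonferroni < alpha:
            out.add(r.trait1)
            out.add(r.trait2)
    return out


def similarity_to_distance(matrix: pd.DataFrame, index_name: str = "") -> pd.DataFrame:
    """Map a similarity matrix to a dissimilarity matrix.

    d = 1 - s for [0, 1]-bounded indices; d = (1 - s)/2 for Pearson (so
    s = -1 maps to 1); values outside [0, 1] (the unnormalised geometric
    index) are first rescaled by the maximum off-diagonal entry.  The
    diagonal is forced to 0.
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("similarity matrix must be square")
    s = matrix.to_numpy(dtype=float).copy()
    if not np.allclose(s, s.T, equal_nan=True):
        raise ValueError("similarity matrix must be symmetric")
    if index_name == "pearson":
        d = (1.0 - s) / 2.0
    else:
        off = s[~np.eye(len(s), dtype=bool)]
        top = np.nanmax(off) if len(off) else 1.0
        if top > 1.0:  # unbounded index: rescale to [0, 1] before inverting
            s = s / top
        d = 1.0 - s
    d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=matrix.index, columns=matrix.columns)


def build_tree(distance: pd.DataFrame, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of a trait-by-trait dissimilarity matrix.

    Leaves are ordered lexicographically by label before linkage so equal
    merge heights resolve deterministically.  ``linkage`` is any scipy
    method valid for precomputed distances ("average", "complete", "single").
    """
    if linkage not in {"average", "complete", "single"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    order = sorted(distance.index)
    dm = distance.loc[order, order].to_numpy(dtype=float)
    condensed = dm[np.triu_indices(len(order), k=1)]
    z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(leaf_labels=list(order), linkage_matrix=z, linkage=linkage)


def cut_tree(tree: ClusterTree, n_clusters: int) -> dict[str, int]:
    """Cut the dendrogram into exactly ``n_clusters`` clusters."""
    if not (1 <= n_clusters <= tree.n_leaves):
        raise ValueError(
            f"n_clusters must be in [1, {tree.n_leaves}], got {n_clusters}"
        )
    labels = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=n_clusters)[:, 0]
    return {trait: int(c) for trait, c in zip(tree.leaf_labels, labels)}


def cluster_entropy(member_categories, kind: str = "gini_simpson") -> float:
    """Entropy E_i of one cluster's category composition.

    ``member_categories`` is one category tuple per member trait (1 or 2
    entries); dual-category traits weight 1/2 per category.  Gini-Simpson:
    1 - sum P_j^2; Shannon-Wiener: -sum P_j ln P_j.  A category-pure cluster
    scores 0 under both.
    """
    member_categories = list(member_categories)
    if not member_categories:
        raise ValueError("cluster has no members")
    weights: dict[str, float] = defaultdict(float)
    for cats in member_categories:
        if isinstance(cats, str):
            cats = (cats,)
        if not cats:
            raise ValueError("every member needs at least one category")
        w = 1.0 / len(cats)
        for c in cats:
            weights[c] += w
    total = sum(weights.values())
    ps = [w / total for w in weights.values()]
    if kind == "gini_simpson":
        return 1.0 - sum(p * p for p in ps)
    if kind == "shannon":
        return -sum(p * math.log(p) for p in ps if p > 0)
    raise ValueError(f"unknown entropy kind {kind!r}")


def heterogeneity_curve(
    tree: ClusterTree,
    categories: dict[str, tuple[str, ...]],
    kinds=("gini_simpson", "shannon"),
    K_range=None,
) -> list[HeterogeneityProfile]:
    """E_K and E'_K over a range of cut sizes K for each entropy kind."""
    if K_range is None:
        K_range = range(2, tree.n_leaves + 1)
    profiles: list[HeterogeneityProfile] = []
    for K in K_range:
        assignment = cut_tree(tree, K)
        clusters: dict[int, list[str]] = defaultdict(list)
        for trait, c in assignment.items():
            clusters[c].append(trait)
        for kind in kinds:
            per = []
            for c in sorted(clusters):
                members = clusters[c]
                e = cluster_entropy([categories[t] for t in members], kind)
                per.append((len(members), e))
            e_k = sum(e for _, e in per) / K
            e_kw = sum(e / n for n, e in per) / K
            profiles.append(
                HeterogeneityProfile(
                    K=K, per_cluster=per, E_K=e_k, E_K_weighted=e_kw, entropy_kind=kind
                )
            )
    return profiles
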