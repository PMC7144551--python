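"""Genotype-posterior distances, neighbor joining, bootstrap and MDS.

Pairwise genetic distances are expected allelic mismatch fractions
computed directly from genotype posterior triples, with pairwise deletion
(each pair uses only the sites where both samples are informative):

    d(i, j) = mean over shared sites of sum_{g,h} P_i(g) P_j(h) |g - h| / 2

Trees are built with Saitou-Nei neighbor joining (ties broken by the
first minimal pair in scan order; negative branch lengths clamped to zero
with the deficit moved to the sister branch). Split support comes from
resampling sites with replacement and recomputing the distance matrix and
tree per replicate. Classical (Torgerson) multidimensional scaling embeds
a distance matrix via eigendecomposition of the double-centered squared
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DISTANCE_KERNEL = np.array(
    [[0.0, 0.5, 1.0], [0.5, 0.0, 0.5], [1.0, 0.5, 0.0]]
)  # |g - h| / 2


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair usable-site counts."""

    values: np.ndarray
    n_sites: np.ndarray
    labels: list[str]

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


def pairwise_distance(
    posteriors: np.ndarray,
    missing: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Expected genotype distance per pair with pairwise deletion.

    ``posteriors`` is sites x samples x 3 genotype posterior triples
    (each summing to 1); ``missing`` marks sample-sites with no data. A
    pair sharing zero sites gets distance NaN and count 0.
    """
    post = np.asarray(posteriors, dtype=float)
    n_sites_total, n_samples, _ = post.shape
    if missing is None:
        missing = np.zeros((n_sites_total, n_samples), dtype=bool)
    missing = np.asarray(missing, dtype=bool)
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(n_samples)]
    transformed = post @ DISTANCE_KERNEL  # sites x samples x 3
    values = np.zeros((n_samples, n_samples))
    counts = np.zeros((n_samples, n_samples), dtype=int)
    for i in range(n_samples):
        counts[i, i] = int((~missing[:, i]).sum())
        for j in range(i + 1, n_samples):
            shared = ~missing[:, i] & ~missing[:, j]
            L = int(shared.sum())
            counts[i, j] = counts[j, i] = L
            if L == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            per_site = (transformed[shared, i, :] * post[shared, j, :]).sum(-1)
            d = float(per_site.sum()) / L
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values=values, n_sites=counts, labels=labels)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Rooted representation of an (unrooted) phylogeny node."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out

    def to_newick(self, include_support: bool = True) -> str:
        def render(node: "TreeNode", length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(render(c, l) for c, l in node.children)
                label = (
                    f"{node.support:g}"
                    if include_support and node.support is not None
                    else ""
                )
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.10g}"

        return render(self, None) + ";"


def nj_tree(dist: DistanceMatrix | np.ndarray, labels: Sequence[str] | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
    with the standard branch-length and distance-update formulas. Ties are
    broken by the first minimal pair in row-major scan order. The last
    three nodes are joined to a trifurcating root by the three-point
    formula. Negative branch lengths are clamped to zero with the deficit
    moved to the sister branch, preserving the pair's path length.
    """
    if isinstance(dist, DistanceMatrix):
        D = np.array(dist.values, dtype=float)
        labels = dist.labels
    else:
        D = np.array(dist, dtype=float)
        labels = list(labels) if labels is not None else [f"s{i}" for i in range(len(D))]
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    while len(nodes) > 3:
        n_act = len(D)
        r = D.sum(1)
        Q = (n_act - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(n_act, k=1)
        flat = Q[iu]
        best = int(flat.argmin())  # first minimum in row-major upper-triangle order
        i, j = int(iu[0][best]), int(iu[1][best])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n_act - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_node = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n_act) if k not in (i, j)]
        D_next = np.empty((len(keep) + 1, len(keep) + 1))
        D_next[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        D_next[-1, : len(keep)] = D_next[: len(keep), -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        D = D_next
        nodes = [nodes[k] for k in keep] + [new_node]
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    return TreeNode(
        children=[
            (nodes[0], max(la, 0.0)),
            (nodes[1], max(lb, 0.0)),
            (nodes[2], max(lc, 0.0)),
        ]
    )


def tree_splits(root: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartitions of an unrooted tree, canonicalized.

    Each internal edge defines a split; the side not containing the
    lexicographically smallest leaf represents it. Trivial splits (single
    leaves or their complements) are omitted.
    """
    all_leaves = root.leaf_names()
    anchor = min(all_leaves)
    n = len(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.name]
        below = []
        for child, _ in node.children:
            below.extend(walk(child))
        if node is not root:
            side = set(below)
            if anchor in side:
                side = set(all_leaves) - side
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset(side))
        return below

    walk(root)
    return splits


def leaf_path_distances(root: TreeNode) -> tuple[np.ndarray, list[str]]:
    """Pairwise leaf-to-leaf path-length matrix of a tree."""
    leaves: list[str] = []
    depths: dict[str, float] = {}
    paths: dict[str, list[int]] = {}

    def walk(node: TreeNode, depth: float, path: tuple[int, ...]) -> None:
        if node.is_leaf:
            leaves.append(node.name)
            depths[node.name] = depth
            paths[node.name] = list(path)
            return
        for ci, (child, length) in enumerate(node.children):
            walk(child, depth + length, path + (id(child),))

    walk(root, 0.0, ())
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[leaves[i]], paths[leaves[j]]
            k = 0
            while k < min(len(pi), len(pj)) and pi[k] == pj[k]:
                k += 1
            # depth of the LCA = sum of shared edge lengths; recompute by walking
            D[i, j] = D[j, i] = depths[leaves[i]] + depths[leaves[j]] - 2 * _prefix_depth(root, pi[:k])
    return D, leaves


def _prefix_depth(root: TreeNode, path: list[int]) -> float:
    node, depth = root, 0.0
    for wanted in path:
        for child, length in node.children:
            if id(child) == wanted:
                node = child
                depth += length
                break
    return depth


def bootstrap_support(
    posteriors: np.ndarray,
    missing: np.ndarray | None,
    labels: Sequence[str],
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, DistanceMatrix]:
    """NJ tree with split supports from site bootstrap.

    Sites are resampled with replacement ``n_replicates`` times; the
    support of each internal split of the full-data tree is the percent
    of replicate trees containing it.
    """
    post = np.asarray(posteriors, dtype=float)
    n_sites = post.shape[0]
    if n_sites < 2:
        raise ValueError("bootstrap requires at least 2 sites")
    miss = (
        np.zeros(post.shape[:2], dtype=bool) if missing is None else np.asarray(missing)
    )
    dist = pairwise_distance(post, miss, labels)
    main = nj_tree(dist)
    main_splits = tree_splits(main)
    counts = {s: 0 for s in main_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep_dist = pairwise_distance(post[idx], miss[idx], labels)
        rep_splits = tree_splits(nj_tree(rep_dist))
        for s in main_splits & rep_splits:
            counts[s] += 1
    all_leaves = main.leaf_names()
    anchor = min(all_leaves)

    def annotate(node: TreeNode) -> list[str]:
        below = []
        if node.is_leaf:
            return [node.name]
        for child, _ in node.children:
            below.extend(annotate(child))
        if node is not main:
            side = set(below)
            if anchor in side:
                side = set(all_leaves) - side
            key = frozenset(side)
            if key in counts:
                node.support = 100.0 * counts[key] / n_replicates
        return below

    annotate(main)
    return main, dist


# ---------------------------------------------------------------------------
# Classical multidimensional scaling
# ---------------------------------------------------------------------------


def classical_mds(
    dist: DistanceMatrix | np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson MDS: embed a distance matrix in k dimensions.

    Double-centers the squared distances, takes the top-k eigenpairs, and
    returns coordinates scaled by the square roots of the eigenvalues.
    Dimensions with non-positive eigenvalues are suppressed (fewer columns
    are returned, with a warning); the full eigenvalue vector is returned
    for diagnostics.
    """
    D = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("need a symmetric distance matrix with zero diagonal")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    top = eigvals[:k]
    usable = top > 1e-12 * max(1.0, abs(eigvals[0]))
    if usable.sum() < k:
        import warnings

        warnings.warn(
            f"only {int(usable.sum())} positive eigenvalues; returning fewer dimensions",
            stacklevel=2,
        )
    dims = np.nonzero(usable)[0]
    coords = eigvecs[:, dims] * np.sqrt(top[dims])
    return coords, eigvals
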