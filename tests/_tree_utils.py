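"""Helpers for tree tests: random additive trees and independent path metrics.

The generator and the distance computations here use networkx only, so
they are independent of the package's neighbor-joining and tree code.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from gbskit.diststruct import TreeNode


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, set[frozenset[str]]]:
    """Random unrooted binary tree with positive branch lengths.

    Returns (labels, additive distance matrix, set of nontrivial splits).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    G = nx.Graph()
    internal = itertools.count()
    center = f"i{next(internal)}"
    for leaf in labels[:3]:
        G.add_edge(leaf, center, weight=float(rng.uniform(0.1, 1.0)))
    for leaf in labels[3:]:
        u, v = list(G.edges())[rng.integers(G.number_of_edges())]
        w = G[u][v]["weight"]
        G.remove_edge(u, v)
        mid = f"i{next(internal)}"
        t = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, weight=t * w)
        G.add_edge(mid, v, weight=(1 - t) * w)
        G.add_edge(mid, leaf, weight=float(rng.uniform(0.1, 1.0)))
    D = np.zeros((n_taxa, n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(G))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = lengths[labels[i]][labels[j]]
    return labels, D, graph_splits(G, labels)


def graph_splits(G: nx.Graph, labels: list[str]) -> set[frozenset[str]]:
    anchor = min(labels)
    splits: set[frozenset[str]] = set()
    for u, v in G.edges():
        H = G.copy()
        H.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(H, u) if n in set(labels)}
        if anchor in side:
            side = set(labels) - side
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(frozenset(side))
    return splits


def tree_to_graph(root: TreeNode) -> nx.Graph:
    """Edge graph of a package tree, for independent path-length checks."""
    G = nx.Graph()
    counter = itertools.count()

    def walk(node: TreeNode) -> str:
        name = node.name if node.is_leaf else f"__int{next(counter)}"
        for child, length in node.children:
            G.add_edge(name, walk(child), weight=length)
        return name

    walk(root)
    return G


def tree_path_distances(root: TreeNode, labels: list[str]) -> np.ndarray:
    G = tree_to_graph(root)
    lengths = dict(nx.all_pairs_dijkstra_path_length(G))
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = lengths[labels[i]][labels[j]]
    return D
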