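"""MST trajectory over cluster centroids, branch detection, branch markers.

The trajectory backbone is the minimum spanning tree of the complete
Euclidean graph over cluster centroids (expression space or any computed
embedding).  Branches are Louvain communities of the tree with edge
affinity ``1 / weight`` — clusters joined by short edges bind tightly,
so communities split preferentially at long edges.  Per-branch marker
statistics compare each branch's cells against all others with a
pooled-variance two-sample t test and Benjamini–Hochberg adjustment
across every (branch, marker) pair.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from cytotrail.model import CytoState
from cytotrail.cluster import cluster_coordinates


@dataclass
class TrajectoryTree:
    """Undirected weighted spanning tree over cluster ids."""

    nodes: list[int]
    edges: list[tuple[int, int, float]]   # (a, b, Euclidean weight), a < b
    space_used: str
    centroids: np.ndarray                 # nodes x dims, aligned with nodes
    branch_labels: Optional[np.ndarray] = None  # per-node, 1-based

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("a spanning tree has exactly |nodes| - 1 edges")

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {n: [] for n in self.nodes}
        for a, b, w in self.edges:
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj

    def leaves(self) -> list[int]:
        """Degree-1 nodes (tree tips)."""
        adj = self.adjacency()
        return [n for n in self.nodes if len(adj[n]) == 1]

    def to_dict(self) -> dict:
        branch = self.branch_labels
        return {
            "nodes": [
                {
                    "id": int(n),
                    "branch": int(branch[i]) if branch is not None else None,
                    "centroid": [float(x) for x in self.centroids[i]],
                }
                for i, n in enumerate(self.nodes)
            ],
            "edges": [{"a": int(a), "b": int(b), "weight": float(w)} for a, b, w in self.edges],
            "space_used": self.space_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryTree":
        nodes = [n["id"] for n in d["nodes"]]
        centroids = np.array([n["centroid"] for n in d["nodes"]], dtype=float)
        branches = None
        if d["nodes"] and d["nodes"][0].get("branch") is not None:
            branches = np.array([n["branch"] for n in d["nodes"]], dtype=int)
        edges = [(e["a"], e["b"], e["weight"]) for e in d["edges"]]
        return cls(
            nodes=nodes,
            edges=edges,
            space_used=d["space_used"],
            centroids=centroids,
            branch_labels=branches,
        )


@dataclass
class MarkerStat:
    """Branch-vs-rest differential statistic for one marker."""

    branch: int
    marker: str
    effect: float      # mean(branch) - mean(rest), transformed units
    statistic: float   # pooled-variance t
    p_raw: float
    p_adj: float = field(default=float("nan"))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def minimum_spanning_tree(
    node_ids: list[int], coords: np.ndarray
) -> list[tuple[int, int, float]]:
    """Kruskal MST of the complete Euclidean graph over ``coords``.

    Edges are processed in (weight, smaller id, larger id) order, which
    makes the tree deterministic even when distances tie exactly.
    """
    n = len(node_ids)
    candidates = []
    for i in range(n):
        diffs = coords[i + 1 :] - coords[i]
        dists = np.sqrt((diffs ** 2).sum(axis=1))
        for j_off, w in enumerate(dists):
            a, b = node_ids[i], node_ids[i + 1 + j_off]
            lo, hi = (a, b) if a < b else (b, a)
            candidates.append((float(w), lo, hi))
    candidates.sort()
    uf = _UnionFind(node_ids)
    edges = []
    for w, a, b in candidates:
        if uf.union(a, b):
            edges.append((a, b, w))
            if len(edges) == n - 1:
                break
    return edges


def build_tree(state: CytoState, space: str = "expression") -> CytoState:
    """Build the MST trajectory over cluster centroids in ``space``."""
    state.require("cluster_labels", "build_tree")
    table = cluster_coordinates(state, space=space)
    if space == "expression":
        coords = table.centroid_expression
    else:
        coords = table.centroid_embedding[space]
    if len(table.cluster_ids) < 2:
        raise ValueError("need at least 2 clusters to build a trajectory")
    edges = minimum_spanning_tree(table.cluster_ids, coords)
    state.invalidate("tree")
    state.tree = TrajectoryTree(
        nodes=list(table.cluster_ids), edges=edges, space_used=space, centroids=coords
    )
    state.record("build_tree", space=space, total_weight=state.tree.total_weight())
    return state


def detect_branches(state: CytoState, resolution: float = 1.0, seed: int = 0) -> CytoState:
    """Partition the tree into branches by Louvain community detection.

    Edge affinity is ``1 / weight`` so that modularity treats short
    (similar-centroid) edges as strong ties.  Branch labels are relabelled
    contiguously from 1, ordered by each branch's smallest cluster id.
    """
    import igraph

    tree = state.require("tree", "detect_branches")
    if len(tree.nodes) == 1:
        tree.branch_labels = np.array([1])
        state.record("detect_branches", resolution=resolution, n_branches=1)
        return state

    index = {n: i for i, n in enumerate(tree.nodes)}
    eps = 1e-12
    g = igraph.Graph(
        n=len(tree.nodes),
        edges=[(index[a], index[b]) for a, b, _ in tree.edges],
    )
    affinities = [1.0 / max(w, eps) for _, _, w in tree.edges]

    rstate = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        communities = g.community_multilevel(weights=affinities, resolution=resolution)
    finally:
        _pyrandom.setstate(rstate)

    membership = np.asarray(communities.membership)
    # contiguous 1-based labels ordered by smallest member cluster id
    order = sorted(set(membership), key=lambda c: min(
        tree.nodes[i] for i in np.flatnonzero(membership == c)
    ))
    relabel = {c: k + 1 for k, c in enumerate(order)}
    tree.branch_labels = np.array([relabel[c] for c in membership], dtype=int)
    state.record(
        "detect_branches", resolution=resolution, seed=seed,
        n_branches=len(order),
    )
    return state


def branch_of_cells(state: CytoState) -> np.ndarray:
    """Per-cell branch id from the per-cluster branch labels."""
    tree = state.require("tree", "branch_of_cells")
    if tree.branch_labels is None:
        raise RuntimeError("run detect_branches before asking for per-cell branches")
    labels = state.require("cluster_labels", "branch_of_cells")
    lookup = {n: int(b) for n, b in zip(tree.nodes, tree.branch_labels)}
    return np.array([lookup[int(c)] for c in labels], dtype=int)


def diff_markers(state: CytoState) -> tuple[list[MarkerStat], list[dict]]:
    """Branch-vs-rest marker statistics with BH adjustment.

    Returns the statistics plus a list of warning records for branches
    with fewer than 2 cells (skipped).
    """
    from statsmodels.stats.multitest import multipletests

    cell_branches = branch_of_cells(state)
    branches = sorted(set(int(b) for b in cell_branches))
    if len(branches) < 2:
        raise ValueError("differential markers need at least 2 branches")

    data = state.matrix.values
    markers = state.matrix.markers
    results: list[MarkerStat] = []
    warnings: list[dict] = []
    for b in branches:
        in_b = cell_branches == b
        if in_b.sum() < 2 or (~in_b).sum() < 2:
            warnings.append({"branch": b, "n_cells": int(in_b.sum()),
                             "reason": "fewer than 2 cells on one side; skipped"})
            continue
        x, y = data[in_b], data[~in_b]
        t_stat, p_val = stats.ttest_ind(x, y, axis=0, equal_var=True)
        eff = x.mean(axis=0) - y.mean(axis=0)
        for j, marker in enumerate(markers):
            results.append(
                MarkerStat(
                    branch=b, marker=marker, effect=float(eff[j]),
                    statistic=float(t_stat[j]), p_raw=float(p_val[j]),
                )
            )
    if results:
        p_adj = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, q in zip(results, p_adj):
            r.p_adj = float(q)
    state.record("diff_markers", n_tests=len(results), n_skipped=len(warnings))
    return results, warnings
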