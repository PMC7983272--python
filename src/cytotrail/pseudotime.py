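"""KNN cell graph, shortest-path pseudotime and intermediate-state walks.

Pseudotime works in four steps: (1) the user names root cells, whose
pseudotime is fixed at zero; (2) a KNN graph connects all kept cells,
edges weighted by Euclidean distance in the chosen space; (3) weighted
shortest-path distances from every root to every cell are computed; and
(4) each cell's mean distance over the ``n`` root cells,

    D_i = (1/n) * sum_j dist_{i,j},

is min-max normalised into a pseudotime,

    pt_i = (D_i - min(D)) / (max(D) - min(D)),

after which roots are forced to exactly zero.  Cells unreachable from
every root receive the maximal finite ``D`` (pseudotime 1) and are
listed in the log.

Intermediate states: the graph is oriented by pseudotime (an edge runs
from its higher-pseudotime endpoint to the lower; equal-pseudotime ties
stay bidirected), and for every (root, leaf) pair one forward shortest
path root -> leaf (ascending orientation) and one backward shortest path
leaf -> root (descending orientation) are walked.  Each cell's count is
the number of walked paths that pass through it; cells with the highest
counts, excluding roots and leaves, are the intermediate-state cells.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sparse_dijkstra

from cytotrail.model import CytoState


@dataclass
class CellGraph:
    """KNN graph over kept cells; optionally oriented by pseudotime."""

    cell_ids: list[str]                       # kept cells, graph order
    edges: list[tuple[int, int, float]]       # undirected, local indices, i < j
    k: int
    space: str
    directed_edges: Optional[list[tuple[int, int, float]]] = None  # u -> v
    n_zero_weight: int = 0
    n_tie_edges: int = 0

    def n_nodes(self) -> int:
        return len(self.cell_ids)

    def sparse(self) -> csr_matrix:
        n = self.n_nodes()
        if not self.edges:
            return csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for i, j, w in self.edges:
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return csr_matrix((vals, (rows, cols)), shape=(n, n))

    def to_dict(self) -> dict:
        return {
            "cell_ids": self.cell_ids,
            "edges": [[int(i), int(j), float(w)] for i, j, w in self.edges],
            "k": self.k,
            "space": self.space,
            "directed_edges": None
            if self.directed_edges is None
            else [[int(u), int(v), float(w)] for u, v, w in self.directed_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellGraph":
        return cls(
            cell_ids=list(d["cell_ids"]),
            edges=[tuple(e) for e in d["edges"]],
            k=d["k"],
            space=d["space"],
            directed_edges=None
            if d.get("directed_edges") is None
            else [tuple(e) for e in d["directed_edges"]],
        )


@dataclass
class WalkResult:
    """Per-cell shortest-path occurrence counts and intermediate flags."""

    counts: np.ndarray          # per cell (full matrix indexing)
    intermediate: np.ndarray    # per cell bool
    params: dict
    skipped_pairs: list = field(default_factory=list)


def default_k(n: int) -> int:
    """ceil(sqrt(n)) capped at 30 — dense enough to connect, sparse enough
    that shortest paths follow the manifold."""
    return int(min(30, max(1, np.ceil(np.sqrt(n)))))


def _space_coords(state: CytoState, space: str) -> np.ndarray:
    kept = state.kept_indices()
    if space == "expression":
        return state.matrix.values[kept]
    if space not in state.embeddings:
        raise KeyError(f"embedding {space!r} not computed; have {sorted(state.embeddings)}")
    coords = state.embeddings[space]
    if coords.shape[0] != kept.size:
        raise RuntimeError(
            f"embedding {space!r} has {coords.shape[0]} rows but {kept.size} cells are kept"
        )
    return coords


def build_knn(
    state: CytoState, k: Optional[int] = None, space: str = "expression"
) -> CytoState:
    """Connect each kept cell to its k nearest neighbours (union-symmetrised).

    Edge weight is the Euclidean distance in ``space``.  Duplicate
    coordinates are allowed; the resulting zero-weight edges are counted
    and noted in the log.
    """
    from sklearn.neighbors import NearestNeighbors

    coords = _space_coords(state, space)
    kept = state.kept_indices()
    n = coords.shape[0]
    if k is None:
        k = default_k(n)
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the {n} kept cells")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dists, neigh = nn.kneighbors(coords)
    edge_set: dict[tuple[int, int], float] = {}
    for i in range(n):
        for d, j in zip(dists[i], neigh[i]):
            if j == i:
                continue
            key = (i, int(j)) if i < j else (int(j), i)
            edge_set.setdefault(key, float(d))
    edges = sorted((i, j, w) for (i, j), w in edge_set.items())
    n_zero = sum(1 for _, _, w in edges if w == 0.0)

    state.invalidate("graph")
    state.cell_graph = CellGraph(
        cell_ids=[state.matrix.cell_ids[i] for i in kept],
        edges=edges,
        k=k,
        space=space,
        n_zero_weight=n_zero,
    )
    state.record("build_knn", k=k, space=space, n_edges=len(edges), zero_weight_edges=n_zero)
    return state


def _resolve_cells(
    state: CytoState,
    cells: Optional[Sequence[str]] = None,
    clusters: Optional[Sequence[int]] = None,
    what: str = "selection",
) -> np.ndarray:
    """Resolve an explicit cell-id or cluster-id selector to a full-matrix mask."""
    mask = np.zeros(state.n_cells, dtype=bool)
    kept = set(state.kept_indices().tolist())
    if cells is not None:
        lookup = {cid: i for i, cid in enumerate(state.matrix.cell_ids)}
        for cid in cells:
            if cid not in lookup:
                raise KeyError(f"{what}: unknown cell id {cid!r}")
            if lookup[cid] not in kept:
                raise KeyError(f"{what}: cell {cid!r} was removed by downsampling")
            mask[lookup[cid]] = True
    if clusters is not None:
        labels = state.require("cluster_labels", what)
        for c in clusters:
            members = np.flatnonzero(labels == int(c))
            members = [m for m in members if m in kept]
            if not members:
                raise KeyError(f"{what}: cluster {c} has no kept cells")
            mask[members] = True
    if not mask.any():
        raise ValueError(f"{what} selected no cells")
    return mask


def def_root_cells(
    state: CytoState,
    cells: Optional[Sequence[str]] = None,
    clusters: Optional[Sequence[int]] = None,
) -> CytoState:
    """Flag the root cells (pseudotime origin); clears downstream results."""
    mask = _resolve_cells(state, cells, clusters, what="def_root_cells")
    state.invalidate("roots")
    state.root_flags = mask
    state.record("def_root_cells", n_roots=int(mask.sum()))
    return state


def run_pseudotime(state: CytoState) -> CytoState:
    """Shortest-path pseudotime from the root cells (steps 3-4)."""
    graph = state.require("cell_graph", "run_pseudotime")
    root_mask = state.require("root_flags", "run_pseudotime")
    kept = state.kept_indices()
    pos = {int(g): i for i, g in enumerate(kept)}  # full index -> graph index
    root_local = np.array(sorted(pos[i] for i in np.flatnonzero(root_mask)))

    mat = graph.sparse()
    dist = _sparse_dijkstra(mat, directed=False, indices=root_local)  # roots x n
    d_i = dist.mean(axis=0)

    finite = np.isfinite(d_i)
    n_unreachable = int((~finite).sum())
    if finite.sum() <= root_local.size and graph.n_nodes() > root_local.size:
        raise RuntimeError(
            "no root cell reaches any non-root cell; the KNN graph is too sparse "
            "— increase k"
        )
    if n_unreachable:
        d_i[~finite] = d_i[finite].max()

    d_min, d_max = float(d_i.min()), float(d_i.max())
    if d_max > d_min:
        pt = (d_i - d_min) / (d_max - d_min)
    else:
        pt = np.zeros_like(d_i)  # degenerate: all distances equal
    pt[root_local] = 0.0

    full_d = np.full(state.n_cells, np.nan)
    full_pt = np.full(state.n_cells, np.nan)
    full_d[kept] = d_i
    full_pt[kept] = pt
    state.invalidate("pseudotime")
    state.distances = full_d
    state.pseudotime = full_pt
    state.record(
        "run_pseudotime",
        n_roots=int(root_local.size),
        n_unreachable=n_unreachable,
        degenerate=bool(d_max <= d_min),
    )
    return state


def def_leaf_cells(
    state: CytoState,
    cells: Optional[Sequence[str]] = None,
    clusters: Optional[Sequence[int]] = None,
    auto_quantile: Optional[float] = None,
) -> CytoState:
    """Flag leaf (terminal) cells.

    ``auto_quantile=q`` flags non-root kept cells whose pseudotime is at or
    above the (1 - q) quantile; explicit selections must not overlap roots.
    """
    pt = state.require("pseudotime", "def_leaf_cells")
    roots = state.require("root_flags", "def_leaf_cells")
    if auto_quantile is not None:
        if not 0 < auto_quantile < 1:
            raise ValueError("auto_quantile must be in (0, 1)")
        kept = state.kept_indices()
        vals = pt[kept]
        cutoff = float(np.quantile(vals, 1 - auto_quantile))
        mask = np.zeros(state.n_cells, dtype=bool)
        mask[kept[vals >= cutoff]] = True
        mask &= ~roots
        if not mask.any():
            raise ValueError("auto leaf selection found no non-root cells")
    else:
        mask = _resolve_cells(state, cells, clusters, what="def_leaf_cells")
        overlap = mask & roots
        if overlap.any():
            ids = [state.matrix.cell_ids[i] for i in np.flatnonzero(overlap)][:5]
            raise ValueError(f"leaf selection overlaps root cells, e.g. {ids}")
    state.invalidate("leaves")
    state.leaf_flags = mask
    state.record("def_leaf_cells", n_leaves=int(mask.sum()))
    return state


def orient_graph(state: CytoState) -> CytoState:
    """Direct each edge from its higher-pseudotime endpoint to the lower.

    Equal-pseudotime edges stay bidirected so ties cannot disconnect the
    walks; their count is logged.  The directed graph supports the
    backward (leaf -> root, descending) walk; the forward walk runs on
    its reverse.
    """
    graph = state.require("cell_graph", "orient_graph")
    pt_full = state.require("pseudotime", "orient_graph")
    kept = state.kept_indices()
    pt = pt_full[kept]

    directed: list[tuple[int, int, float]] = []
    ties = 0
    for i, j, w in graph.edges:
        if pt[i] > pt[j]:
            directed.append((i, j, w))
        elif pt[j] > pt[i]:
            directed.append((j, i, w))
        else:
            directed.append((i, j, w))
            directed.append((j, i, w))
            ties += 1
    graph.directed_edges = directed
    graph.n_tie_edges = ties
    state.invalidate("walk")
    state.record("orient_graph", n_directed=len(directed), tie_edges=ties)
    return state


def _dijkstra_path(
    adj: dict[int, list[tuple[int, float]]],
    source: int,
    target: int,
    ids: list[str],
) -> Optional[list[int]]:
    """Dijkstra with a deterministic tie-break: among equal-distance
    relaxations each node keeps the predecessor with the lexicographically
    smallest cell id.  Returns the node path or None if unreachable."""
    dist: dict[int, float] = {source: 0.0}
    pred: dict[int, Optional[int]] = {source: None}
    done: set[int] = set()
    heap: list[tuple[float, str, int]] = [(0.0, ids[source], source)]
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == target:
            break
        for v, w in adj.get(u, ()):
            nd = d + w
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, ids[v], v))
            elif v not in done and abs(nd - dist[v]) <= 1e-15:
                if pred[v] is None or ids[u] < ids[pred[v]]:
                    pred[v] = u
    if target not in done:
        return None
    path = [target]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    return path[::-1]


def run_walk(state: CytoState, quantile: float = 0.8) -> CytoState:
    """Forward and backward walks between every root and leaf.

    For each (root r, leaf l) pair, one forward shortest path r -> l on
    the ascending orientation and one backward shortest path l -> r on
    the descending orientation are walked (weighted, deterministic
    tie-break).  A cell's count is the number of walked paths containing
    it; non-root, non-leaf cells whose count reaches the ``quantile``
    percentile of positive counts are flagged intermediate.  Pairs with
    no path are recorded and skipped.
    """
    graph = state.require("cell_graph", "run_walk")
    if graph.directed_edges is None:
        raise RuntimeError("run orient_graph before run_walk")
    roots_full = state.require("root_flags", "run_walk")
    leaves_full = state.require("leaf_flags", "run_walk")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")

    kept = state.kept_indices()
    pos = {int(g): i for i, g in enumerate(kept)}
    roots = sorted(pos[i] for i in np.flatnonzero(roots_full))
    leaves = sorted(pos[i] for i in np.flatnonzero(leaves_full))
    ids = graph.cell_ids

    down: dict[int, list[tuple[int, float]]] = {}
    up: dict[int, list[tuple[int, float]]] = {}
    for u, v, w in graph.directed_edges:
        down.setdefault(u, []).append((v, w))
        up.setdefault(v, []).append((u, w))

    counts = np.zeros(graph.n_nodes(), dtype=int)
    skipped: list = []
    for r in roots:
        for l in leaves:
            fwd = _dijkstra_path(up, r, l, ids)  # ascending pseudotime
            if fwd is None:
                skipped.append({"root": ids[r], "leaf": ids[l], "direction": "forward"})
            else:
                counts[fwd] += 1
            bwd = _dijkstra_path(down, l, r, ids)  # descending pseudotime
            if bwd is None:
                skipped.append({"root": ids[r], "leaf": ids[l], "direction": "backward"})
            else:
                counts[bwd] += 1

    interior = np.ones(graph.n_nodes(), dtype=bool)
    interior[roots] = False
    interior[leaves] = False
    positive = counts[interior & (counts > 0)]
    inter_local = np.zeros(graph.n_nodes(), dtype=bool)
    if positive.size:
        cutoff = float(np.quantile(positive, quantile))
        inter_local = interior & (counts >= cutoff) & (counts > 0)

    full_counts = np.zeros(state.n_cells, dtype=int)
    full_inter = np.zeros(state.n_cells, dtype=bool)
    full_counts[kept] = counts
    full_inter[kept] = inter_local
    state.walk = WalkResult(
        counts=full_counts,
        intermediate=full_inter,
        params={
            "n_roots": len(roots),
            "n_leaves": len(leaves),
            "quantile": quantile,
            "directions": ["forward", "backward"],
        },
        skipped_pairs=skipped,
    )
    state.record(
        "run_walk",
        quantile=quantile,
        n_paths=2 * len(roots) * len(leaves) - len(skipped),
        n_skipped=len(skipped),
        n_intermediate=int(inter_local.sum()),
    )
    return state
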