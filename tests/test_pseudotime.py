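"""KNN graph, shortest-path pseudotime and the root/leaf walk machinery."""

import numpy as np
import pytest

import cytotrail as ct
from cytotrail.pseudotime import CellGraph, default_k


def _graph_state(n, edges, roots, ids=None):
    """State with an injected cell graph (local indices) and root flags."""
    ids = ids or [f"c{i + 1:02d}" for i in range(n)]
    rng = np.random.default_rng(0)
    m = ct.EventMatrix(rng.normal(size=(n, 2)), ["M1", "M2"], ids, ["s"] * n)
    state = ct.create_state(m)
    state.cell_graph = CellGraph(
        cell_ids=ids,
        edges=[(min(i, j), max(i, j), float(w)) for i, j, w in edges],
        k=1,
        space="expression",
    )
    ct.def_root_cells(state, cells=[ids[i] for i in roots])
    return state


def _line_state(positions, extra_dim=0.0):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    values = np.column_stack([positions, np.full(n, extra_dim)])
    m = ct.EventMatrix(values, ["M1", "M2"], [f"c{i:03d}" for i in range(n)], ["s"] * n)
    return ct.create_state(m)


def _floyd_warshall(n, edges):
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j, w in edges:
        d[i, j] = d[j, i] = min(d[i, j], w)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


class TestBuildKnn:
    def test_collinear_points_yield_the_path(self):
        state = _line_state([0.0, 1.0, 2.0])
        ct.build_knn(state, k=1)
        assert state.cell_graph.edges == [(0, 1, 1.0), (1, 2, 1.0)]

    def test_k_n_minus_one_is_complete(self):
        rng = np.random.default_rng(1)
        state = _line_state(rng.uniform(size=6))
        ct.build_knn(state, k=5)
        assert len(state.cell_graph.edges) == 15

    def test_duplicate_points_flag_zero_weight_edges(self):
        state = _line_state([0.0, 0.0, 5.0])
        ct.build_knn(state, k=1)
        assert state.cell_graph.n_zero_weight == 1
        assert state.log[-1]["params"]["zero_weight_edges"] == 1

    def test_k_bounds(self):
        state = _line_state([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ct.build_knn(state, k=0)
        with pytest.raises(ValueError):
            ct.build_knn(state, k=3)

    def test_default_k_formula(self):
        assert default_k(4) == 2
        assert default_k(100) == 10
        assert default_k(100_000) == 30


class TestRootSelection:
    def test_cluster_selector_flags_kept_members(self, small_matrix):
        state = ct.create_state(small_matrix)
        ct.run_cluster(state, "kmeans", k=3, seed=0)
        ct.def_root_cells(state, clusters=[2])
        expected = state.cluster_labels == 2
        np.testing.assert_array_equal(state.root_flags, expected)

    def test_unknown_cell_is_named(self, small_matrix):
        state = ct.create_state(small_matrix)
        with pytest.raises(KeyError, match="nosuch"):
            ct.def_root_cells(state, cells=["nosuch"])

    def test_empty_selection_rejected(self, small_matrix):
        state = ct.create_state(small_matrix)
        with pytest.raises((ValueError, TypeError)):
            ct.def_root_cells(state, cells=[])


class TestRunPseudotime:
    def test_path_graph_hand_example(self):
        # A - B - C with unit weights, root A: D = (0, 1, 2), pt = (0, .5, 1)
        state = _graph_state(3, [(0, 1, 1.0), (1, 2, 1.0)], roots=[0])
        ct.run_pseudotime(state)
        np.testing.assert_allclose(state.distances, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(state.pseudotime, [0.0, 0.5, 1.0])

    def test_two_end_roots_degenerate_to_zero(self):
        # roots at both ends of A - B - C: every D_i equals 1
        state = _graph_state(3, [(0, 1, 1.0), (1, 2, 1.0)], roots=[0, 2])
        ct.run_pseudotime(state)
        np.testing.assert_allclose(state.distances, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(state.pseudotime, 0.0)

    def test_all_roots_all_zero(self):
        state = _graph_state(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)], roots=[0, 1, 2, 3])
        ct.run_pseudotime(state)
        np.testing.assert_allclose(state.pseudotime, 0.0)

    def test_roots_forced_to_exact_zero(self):
        # root B sits mid-path; its own D is positive but pt must still be 0
        state = _graph_state(3, [(0, 1, 1.0), (1, 2, 3.0)], roots=[1])
        ct.run_pseudotime(state)
        assert state.pseudotime[1] == 0.0
        assert state.pseudotime[2] == 1.0

    def test_unreachable_cells_map_to_one(self):
        state = _graph_state(4, [(0, 1, 1.0), (2, 3, 1.0)], roots=[0])
        ct.run_pseudotime(state)
        assert state.pseudotime[2] == 1.0 and state.pseudotime[3] == 1.0
        assert state.log[-1]["params"]["n_unreachable"] == 2

    def test_isolated_root_errors(self):
        state = _graph_state(3, [(1, 2, 1.0)], roots=[0])
        with pytest.raises(RuntimeError, match="increase k"):
            ct.run_pseudotime(state)

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 61))
            # random connected graph: a random spanning path plus extra edges
            perm = rng.permutation(n)
            edges = {}
            for a, b in zip(perm[:-1], perm[1:]):
                i, j = (int(a), int(b)) if a < b else (int(b), int(a))
                edges[(i, j)] = float(rng.uniform(0.1, 5))
            for _ in range(2 * n):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    key = (int(min(i, j)), int(max(i, j)))
                    edges.setdefault(key, float(rng.uniform(0.1, 5)))
            edge_list = [(i, j, w) for (i, j), w in edges.items()]
            n_roots = int(rng.integers(1, max(2, n // 5)))
            roots = sorted(rng.choice(n, size=n_roots, replace=False).tolist())
            state = _graph_state(n, edge_list, roots=roots)
            ct.run_pseudotime(state)

            d = _floyd_warshall(n, edge_list)
            d_i = d[:, roots].mean(axis=1)
            expected = (d_i - d_i.min()) / (d_i.max() - d_i.min()) if d_i.max() > d_i.min() else np.zeros(n)
            expected[roots] = 0.0
            np.testing.assert_allclose(state.distances, d_i, atol=1e-9)
            np.testing.assert_allclose(state.pseudotime, expected, atol=1e-9)

    def test_monotone_along_a_line(self):
        positions = np.linspace(0, 10, 40)
        state = _line_state(positions)
        ct.build_knn(state, k=2)
        ct.def_root_cells(state, cells=["c000"])
        ct.run_pseudotime(state)
        assert (np.diff(state.pseudotime) > 0).all()

    def test_range_invariants(self, star3):
        matrix, truth = star3
        state = ct.create_state(matrix)
        ct.build_knn(state)
        root = state.matrix.cell_ids[int(np.argmin(truth.pseudotime))]
        ct.def_root_cells(state, cells=[root])
        ct.run_pseudotime(state)
        pt = state.pseudotime
        assert pt.min() == 0.0 and pt.max() == pytest.approx(1.0)
        state.check_invariants()


class TestLeafSelection:
    def _ready_state(self):
        state = _line_state(np.linspace(0, 5, 20))
        ct.build_knn(state, k=2)
        ct.def_root_cells(state, cells=["c000"])
        ct.run_pseudotime(state)
        return state

    def test_auto_flags_argmax(self):
        state = self._ready_state()
        ct.def_leaf_cells(state, auto_quantile=0.04)
        assert state.leaf_flags.sum() == 1
        assert state.leaf_flags[int(np.argmax(state.pseudotime))]

    def test_explicit_selection(self):
        state = self._ready_state()
        ct.def_leaf_cells(state, cells=["c018", "c019"])
        assert state.leaf_flags.sum() == 2

    def test_root_overlap_rejected(self):
        state = self._ready_state()
        with pytest.raises(ValueError, match="overlap"):
            ct.def_leaf_cells(state, cells=["c000"])


class TestOrientGraph:
    def test_higher_pseudotime_points_down(self):
        state = _graph_state(3, [(0, 1, 1.0), (1, 2, 1.0)], roots=[0])
        ct.run_pseudotime(state)
        ct.orient_graph(state)
        directed = set((u, v) for u, v, _ in state.cell_graph.directed_edges)
        assert directed == {(1, 0), (2, 1)}

    def test_ties_stay_bidirected(self):
        # diamond: both middles at equal pseudotime, no edge between them
        edges = [(0, 1, 1.0), (0, 2, 1.0), (1, 3, 1.0), (2, 3, 1.0)]
        state = _graph_state(4, edges, roots=[0])
        ct.run_pseudotime(state)
        ct.orient_graph(state)
        assert state.cell_graph.n_tie_edges == 0
        # force a tie through duplicate geometry: chain with equal-pt pair
        state2 = _graph_state(3, [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 0.5)], roots=[0])
        ct.run_pseudotime(state2)
        ct.orient_graph(state2)
        directed = set((u, v) for u, v, _ in state2.cell_graph.directed_edges)
        assert (1, 2) in directed and (2, 1) in directed
        assert state2.cell_graph.n_tie_edges == 1

    def test_antisymmetric_for_unequal_pseudotime(self):
        rng = np.random.default_rng(3)
        state = _line_state(rng.uniform(size=25))
        ct.build_knn(state, k=3)
        ct.def_root_cells(state, cells=[state.matrix.cell_ids[0]])
        ct.run_pseudotime(state)
        ct.orient_graph(state)
        graph = state.cell_graph
        pt = state.pseudotime
        seen = set((u, v) for u, v, _ in graph.directed_edges)
        for u, v in list(seen):
            if pt[u] != pt[v]:
                assert (v, u) not in seen


def _oracle_walk_path(directed_adj, source, target, ids):
    """Independent shortest-path oracle: networkx distances + lexicographic
    predecessor backtracking."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(len(ids)))
    for u, nbrs in directed_adj.items():
        for v, w in nbrs:
            g.add_edge(u, v, weight=w)
    try:
        dist = nx.single_source_dijkstra_path_length(g, source)
    except nx.NodeNotFound:
        return None
    if target not in dist:
        return None
    path = [target]
    while path[-1] != source:
        u = path[-1]
        cands = [
            p
            for p in g.predecessors(u)
            if p in dist and abs(dist[p] + g[p][u]["weight"] - dist[u]) <= 1e-12
        ]
        path.append(min(cands, key=lambda p: ids[p]))
    return path[::-1]


def _oracle_counts(state):
    """Exhaustive enumeration of all walked paths under the tie-break."""
    graph = state.cell_graph
    ids = graph.cell_ids
    down, up = {}, {}
    for u, v, w in graph.directed_edges:
        down.setdefault(u, []).append((v, w))
        up.setdefault(v, []).append((u, w))
    roots = sorted(np.flatnonzero(state.root_flags).tolist())
    leaves = sorted(np.flatnonzero(state.leaf_flags).tolist())
    counts = np.zeros(len(ids), dtype=int)
    for r in roots:
        for l in leaves:
            fwd = _oracle_walk_path(up, r, l, ids)
            if fwd is not None:
                counts[fwd] += 1
            bwd = _oracle_walk_path(down, l, r, ids)
            if bwd is not None:
                counts[bwd] += 1
    return counts


class TestRunWalk:
    def _prepare(self, n, edges, roots, leaves):
        state = _graph_state(n, edges, roots=roots)
        ct.run_pseudotime(state)
        ct.def_leaf_cells(state, cells=[state.matrix.cell_ids[i] for i in leaves])
        ct.orient_graph(state)
        return state

    def test_chain_interior_counted_twice(self):
        state = self._prepare(3, [(0, 1, 1.0), (1, 2, 1.0)], roots=[0], leaves=[2])
        ct.run_walk(state)
        np.testing.assert_array_equal(state.walk.counts, [2, 2, 2])
        assert state.walk.intermediate[1]
        assert not state.walk.intermediate[0] and not state.walk.intermediate[2]

    def test_adjacent_root_and_leaf_no_intermediate(self):
        state = self._prepare(2, [(0, 1, 1.0)], roots=[0], leaves=[1])
        ct.run_walk(state)
        assert state.walk.intermediate.sum() == 0
        np.testing.assert_array_equal(state.walk.counts, [2, 2])

    def test_diamond_tie_break_is_deterministic(self):
        edges = [(0, 1, 1.0), (0, 2, 1.0), (1, 3, 1.0), (2, 3, 1.0)]
        state = self._prepare(4, edges, roots=[0], leaves=[3])
        ct.run_walk(state)
        # both directions resolve the tie to the lexicographically smaller c02
        np.testing.assert_array_equal(state.walk.counts, [2, 2, 0, 2])
        np.testing.assert_array_equal(state.walk.counts, _oracle_counts(state))

    def test_fig_style_fixture_bottlenecks(self):
        # 10 cells: two adjacent roots, a dead-end decoy (3), slow parallel
        # arcs (5, 6) and (8), cut vertices 4 and 7, terminal cell 10
        edges = [
            (0, 1, 1.0),   # the two roots
            (0, 2, 1.0),   # decoy dead end
            (0, 3, 1.0), (1, 3, 1.0),          # roots feed the bottleneck 4
            (3, 6, 1.0),                        # direct 4 - 7
            (3, 4, 0.9), (4, 6, 0.9),           # slower parallel via 5
            (3, 5, 0.95), (5, 6, 0.95),         # slower parallel via 6
            (6, 8, 1.0), (8, 9, 1.0),           # 7 - 9 - 10 main line
            (6, 7, 1.1), (7, 9, 1.1),           # slower parallel via 8
        ]
        state = _graph_state(10, edges, roots=[0, 1])
        ct.run_pseudotime(state)
        assert int(np.argmax(state.pseudotime)) == 9  # cell 10 is terminal
        ct.def_leaf_cells(state, auto_quantile=0.05)
        assert state.leaf_flags[9] and state.leaf_flags.sum() == 1
        ct.orient_graph(state)
        ct.run_walk(state)
        counts = state.walk.counts
        np.testing.assert_array_equal(counts, _oracle_counts(state))
        interior = np.ones(10, dtype=bool)
        interior[[0, 1, 9]] = False
        top = set(np.flatnonzero(interior & (counts == counts[interior].max())))
        assert {3, 6} <= top  # the cut vertices carry every walked path
        assert state.walk.intermediate[3] and state.walk.intermediate[6]

    def test_random_graphs_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = 15
            perm = rng.permutation(n)
            edges = {}
            for a, b in zip(perm[:-1], perm[1:]):
                i, j = sorted((int(a), int(b)))
                edges[(i, j)] = float(rng.uniform(0.5, 2))
            for _ in range(n):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    edges.setdefault(tuple(sorted((int(i), int(j)))), float(rng.uniform(0.5, 2)))
            edge_list = [(i, j, w) for (i, j), w in edges.items()]
            state = _graph_state(n, edge_list, roots=[int(perm[0])])
            ct.run_pseudotime(state)
            leaf = int(np.argmax(state.pseudotime))
            ct.def_leaf_cells(state, cells=[state.matrix.cell_ids[leaf]])
            ct.orient_graph(state)
            ct.run_walk(state)
            np.testing.assert_array_equal(state.walk.counts, _oracle_counts(state))

    def test_count_conservation(self):
        # total count equals the summed node-length of all walked paths
        edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (1, 3, 2.5)]
        state = self._prepare(4, edges, roots=[0], leaves=[3])
        ct.run_walk(state)
        graph = state.cell_graph
        down, up = {}, {}
        for u, v, w in graph.directed_edges:
            down.setdefault(u, []).append((v, w))
            up.setdefault(v, []).append((u, w))
        total = 0
        fwd = _oracle_walk_path(up, 0, 3, graph.cell_ids)
        bwd = _oracle_walk_path(down, 3, 0, graph.cell_ids)
        total += len(fwd) + len(bwd)
        assert state.walk.counts.sum() == total

    def test_unreachable_pair_skipped_not_fatal(self):
        state = _graph_state(4, [(0, 1, 1.0), (2, 3, 1.0)], roots=[0])
        ct.run_pseudotime(state)
        ct.def_leaf_cells(state, cells=[state.matrix.cell_ids[3]])
        ct.orient_graph(state)
        ct.run_walk(state)
        assert len(state.walk.skipped_pairs) == 2
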