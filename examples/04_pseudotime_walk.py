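"""Pseudotime from root cells and intermediate-state scoring by walks.

On the three-armed star data: build the KNN cell graph, declare the
earliest cluster as root cells, compute shortest-path pseudotime,
auto-select leaves, orient the graph by pseudotime and walk the
root-to-leaf shortest paths.  Cells carrying the most walked paths are
the intermediate states (here: cells near the branch point).
"""

import numpy as np
from scipy.stats import spearmanr

import cytotrail as ct

matrix, truth = ct.simulate_tree_data(
    ct.star3_topology(), n_per_segment=200, n_markers=10, noise_sd=0.1, seed=7
)
state = ct.create_state(matrix)
ct.run_cluster(state, method="som", seed=7)
ct.build_knn(state, space="expression")        # k = ceil(sqrt(n)), capped at 30

# root = the cluster whose cells are earliest in the true process; in real
# data this is the user's biological knowledge (e.g. the HSPC cluster)
labels = state.cluster_labels
cluster_pt = {c: truth.pseudotime[labels == c].mean() for c in np.unique(labels)}
root_cluster = min(cluster_pt, key=cluster_pt.get)
ct.def_root_cells(state, clusters=[int(root_cluster)])

ct.run_pseudotime(state)
rho = spearmanr(truth.pseudotime, state.pseudotime).statistic
print(f"pseudotime range [{state.pseudotime.min():.2f}, {state.pseudotime.max():.2f}], "
      f"Spearman vs truth: {rho:.3f}")

ct.def_leaf_cells(state, auto_quantile=0.02)   # top 2% pseudotime = leaves
ct.orient_graph(state)
ct.run_walk(state, quantile=0.8)
walk = state.walk
inter = np.flatnonzero(walk.intermediate)
print(f"leaves: {int(state.leaf_flags.sum())}, walked paths touch "
      f"{int((walk.counts > 0).sum())} cells, intermediate: {len(inter)}")
print(f"intermediate cells' true pseudotime: "
      f"median {np.median(truth.pseudotime[inter]):.2f} "
      f"(roots at 0, branch point at 0.5, tips at 1)")
# intermediate cells are the interior cells the walked root-to-leaf paths
# traverse most often - transit corridors between the origin and the fates
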