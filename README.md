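# cytotrail

Trajectory inference, pseudotime estimation and intermediate-state
scoring for flow and mass cytometry data.

Cytometry experiments measure tens of protein markers on up to millions
of single cells.  When the cells span a continuous biological process —
hematopoietic differentiation, directed differentiation of stem cells, a
reprogramming time course — the analyst wants more than cell-type gates:
an ordering of cells along the process (*pseudotime*), the branching
structure of the fates (*trajectory*), and the transient cells that sit
between origin and fate (*intermediate states*).  `cytotrail` provides
that workflow end to end for people who work with FCS files or plain
cells × markers matrices: preprocessing, clustering, embedding,
tree-shaped trajectory construction, pseudotime and walk-based
intermediate-state scoring, with a synthetic branching-data generator so
every stage can be validated against a known ground truth.

## The method

**Preprocessing.** Events are compensated by solving `X′ · S = X` for
the spillover matrix `S` (from `$SPILLOVER` or supplied), gated with
axis-aligned intervals, transformed (`arcsinh(x / cofactor)` by
default), and merged across samples with a fixed number of cells drawn
per sample so every time point contributes equally.

**Clustering and trajectory.** Cells are clustered by a self-organizing
map (default 6×6 grid), k-means or Ward hierarchical clustering.  The
centroid of cluster *j* in dimension *i* is the arithmetic mean over its
cells,

    coord(i, j) = (1/n) Σ_k x_{i,k},   k ∈ cluster j,

computed either on marker expression or on an embedding (PCA, tSNE,
diffusion map, UMAP).  The trajectory is the minimum spanning tree of
the complete Euclidean graph over the centroids; Louvain communities of
the tree (edge affinity 1/distance) are the branches, and each branch is
profiled by branch-vs-rest marker statistics with Benjamini–Hochberg
adjustment.

**Pseudotime.**  With user-designated root cells (the biological
origin), a k-nearest-neighbour graph connects all cells and, per cell
*i*,

    D_i = (1/n) Σ_j dist(i, j),   j over the n root cells,
    pt_i = (D_i − min D) / (max D − min D),

where `dist` is the weighted shortest-path distance.  Root cells are
pinned at pseudotime 0.

**Intermediate states.**  Each KNN edge is oriented from its
higher-pseudotime endpoint to the lower.  For every (root, leaf) pair
one forward (ascending) and one backward (descending) shortest path is
walked; a cell's score is the number of walked paths through it, and the
top-scoring interior cells are flagged as intermediate states — the
corridors every route from origin to fate must traverse.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import cytotrail as ct

# three-armed differentiation tree, 200 cells per segment, known truth
matrix, truth = ct.simulate_tree_data(
    ct.star3_topology(), n_per_segment=200, n_markers=10, noise_sd=0.1, seed=7
)
state = ct.create_state(matrix)
ct.run_cluster(state, method="som", seed=7)          # default 6x6 grid
ct.build_tree(state, space="expression")
ct.detect_branches(state, seed=7)
ct.build_knn(state, space="expression")

labels = state.cluster_labels
earliest = min(np.unique(labels),
               key=lambda c: truth.pseudotime[labels == c].mean())
ct.def_root_cells(state, clusters=[int(earliest)])
ct.run_pseudotime(state)
print(spearmanr(truth.pseudotime, state.pseudotime).statistic)

ct.def_leaf_cells(state, auto_quantile=0.02)
ct.orient_graph(state)
ct.run_walk(state)
print(int(state.walk.intermediate.sum()))
```

This prints

```
0.9952...
25
```

a Spearman correlation of 0.995 between true and estimated pseudotime,
and 25 intermediate-state cells, all of which lie on the true
root-to-leaf paths.  The scripts in `examples/` walk through each
capability (preprocessing FCS files, clustering and embedding, the
trajectory tree, pseudotime and walks) with printed, annotated output.

## Command line

The same workflow runs from a shell against a persisted state directory:

```bash
cytotrail simulate --topology star3 --n 200 --noise 0.1 --seed 7 --out fixtures/ --fcs
cytotrail preprocess --fcs fixtures/sample.fcs --transform none --out run/
cytotrail cluster --state run/ --method som --seed 7
cytotrail tree --state run/ && cytotrail branches --state run/
cytotrail pseudotime --state run/ --roots cluster:15
cytotrail walk --state run/ --leaves auto:0.02
cytotrail report --state run/
```

`cytotrail run --config cfg.json --input data.fcs --out run/` chains all
stages; re-running with a changed parameter resumes from the first
affected stage.

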