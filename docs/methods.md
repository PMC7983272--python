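# Methods

This note documents the models and procedures implemented in
`cytotrail`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Preprocessing

FCS 3.0/3.1 single-dataset files are parsed directly: float (`F`/`D`)
and integer (`I`) storage are supported, and integer parameters stored
on a log scale (`$PnE = f1,f2` with `f1 > 0`) are linearized as
`f2 · 10^(f1·x/$PnR)` on read.  The spillover matrix is read from
`$SPILLOVER` (or the older `SPILL`), oriented rows = detector,
columns = fluorochrome.  Compensation solves `X′ · S = X`
(equivalently `X′ = X S⁻¹`) for the channels named by the matrix;
unnamed channels pass through.  A singular spillover raises rather than
silently pseudo-inverting.

Gates are closed axis-aligned intervals, intersected; the preprocessing
order is compensate → gate → transform, the convention of manual
cytometry analysis (gates are defined on compensated linear
intensities).  The default transform is `arcsinh(x / cofactor)` with
cofactor 5, the mass-cytometry convention; 150 is typical for
conventional flow, and `log10`/`none` are available.  `log10` clips its
argument at 1 so negative compensated values map to 0 instead of NaN.

Merging draws `min(n_per_sample, n_i)` cells uniformly without
replacement from each sample (default 2,000 per sample).  The random
substream for each sample is derived from the global seed plus a hash of
the sample's label, so reordering input files cannot change which cells
are drawn.

## Clustering

The default clusterer is an online self-organizing map on a 6×6
rectangular grid (36 prototypes), `rlen` = 8 passes, learning rate
decaying linearly 0.05 → 0.01, Gaussian neighbourhood radius decaying
linearly from half the grid diagonal to ~0 so the final stretch of
training is winner-only and prototypes settle on local means.  A cell's
cluster is the index of its nearest prototype (Euclidean), so the
cluster count is at most `xdim · ydim`.

Two SOM-specific choices deserve note.  Prototypes are initialised on
sampled data rows.  After training, any *dead* prototype — one that wins
no cell — is re-seeded on the cell with the largest quantisation error
and the map is refined with two winner-mean (Lloyd) steps, repeated up
to five rounds.  A dead unit can never recover on its own once the
neighbourhood has shrunk, and on strongly multimodal data (more modes
than grid nodes) plain online training routinely strands several units;
re-seeding is the same empty-cluster policy k-means implementations use
and guarantees the map's capacity is spent on the data.

k-means uses k-means++ initialisation with 10 restarts; hierarchical
clustering uses Ward linkage on Euclidean distances.  Algorithms beyond
these (e.g. PhenoGraph-style community clustering, clara) plug in as a
callable mapping the matrix to integer labels (`method="custom"`).

Cluster-dependent downsampling keeps `max(1, ceil(fraction · size))`
cells per cluster, each cluster with its own deterministic substream, so
rare populations are never dropped entirely.  Cell-level tSNE/UMAP/
diffusion-map embeddings refuse to run above 100,000 kept cells unless
forced; downsampling first is the intended route.

## Embeddings

PCA is an exact centred SVD with a deterministic sign convention
(largest-magnitude loading positive).  tSNE (scikit-learn) and UMAP are
seeded; tSNE perplexity adapts to small inputs as `min(30, (n−1)/3)`.
The diffusion map builds a Gaussian kernel
`K_ij = exp(−d_ij²/(2σ²))`, applies density normalisation (dividing by
the outer product of row sums, the α = 1 convention that removes
sampling-density bias), row-normalises to a Markov matrix and embeds by
the top non-trivial right eigenvectors scaled by their eigenvalues,
solved through the symmetric conjugate for numerical stability.  σ
defaults to the median pairwise distance ("auto").

## Trajectory tree and branches

Cluster centroids are arithmetic means of member cells — all clustered
cells in expression space, the kept (downsampled) cells in an embedding
space, since an embedding only exists for kept cells.  The trajectory is
the MST of the complete Euclidean graph over centroids, computed by
Kruskal with edges ordered by (weight, smaller cluster id, larger
cluster id) so exact distance ties cannot make the tree depend on input
order.

Branches are Louvain communities of the tree with edge affinity
`1/weight` — modularity treats larger values as stronger ties, so the
reciprocal makes short (similar-centroid) edges bind and splits fall
preferentially at long edges.  The resolution parameter (default 1.0) is
exposed; the backend RNG is seeded for determinism and labels are
relabelled contiguously from 1, ordered by smallest member cluster id.

Differential markers per branch use a pooled-variance two-sample t test
of the branch's cells against all other cells, per marker, with
Benjamini–Hochberg adjustment across all (branch, marker) pairs.  With
cytometry-scale panels (≤ ~50 markers) and thousands of cells per
branch, empirical-Bayes variance moderation would change essentially
nothing, so the plain t test is used; branches with fewer than two cells
are skipped with a warning record rather than an error.

## Pseudotime

Given root cells (a biological designation, not an inference), the KNN
graph over kept cells uses Euclidean distances in the chosen space,
symmetrised by union, `k = ceil(sqrt(n))` capped at 30 by default —
dense enough to connect a manifold sample, sparse enough that shortest
paths follow it.  Per cell, `D_i` is the mean weighted shortest-path
distance to the `n` root cells and pseudotime is the min–max
normalisation of `D`; root cells are then pinned to exactly 0 (a root's
own `D_i` is positive whenever there are several roots).

Degenerate and pathological cases are handled explicitly rather than
left to NaN: if every `D_i` is equal (e.g. every cell is a root) all
pseudotimes are 0; a cell unreachable from every root receives the
maximal finite `D` (hence pseudotime 1) and is listed in the log —
keeping the field total without inventing connectivity; if no root
reaches any non-root cell the run fails with advice to raise `k`.

## Walks and intermediate states

The graph is oriented by the rule "an edge may be traversed from its
higher-pseudotime endpoint to the lower".  Taken literally this only
permits walks that descend pseudotime, which serves the backward
(leaf → root) walk; the forward (root → leaf) walk runs on the reversed
orientation, i.e. ascending pseudotime.  Equal-pseudotime edges stay
bidirected — dropping a direction could disconnect walks — and their
count is logged.

Leaves default to the top 2% of pseudotime (`auto_quantile = 0.02`),
excluding roots; explicit cell or cluster selections are validated
against the root set.  For every (root, leaf) pair one forward and one
backward weighted shortest path is computed by Dijkstra with a
deterministic tie-break: among equal-distance relaxations a node keeps
the predecessor with the lexicographically smallest cell id, making path
choice — and therefore every count — reproducible.  A cell's walk count
is the number of walked paths containing it.  Interior cells (neither
root nor leaf) whose count reaches the 80th percentile of positive
interior counts are flagged intermediate; the quantile is a parameter
(`quantile`, CLI `--walk-quantile`).  Pairs with no connecting path are
recorded and skipped, not fatal.

On dense KNN graphs the top-count cells concentrate where paths funnel —
immediately around roots' exits, branch corridors and leaf approaches —
rather than exactly at a geometric branch point; on sparse graphs they
are the cut vertices.  Both are faithful readings of "cells most
frequently on the walked paths".

## Synthetic data

`simulate_tree_data` samples cells along a rooted tree of segments.
Each segment carries a linear marker program (start and end mean
vector); a cell at position `u ∈ [0,1)` has mean
`(1−u)·start + u·end` plus independent Gaussian noise, and its true
pseudotime is its depth along the root path scaled to [0, 1].  Children
start exactly at the parent's end (continuity at branch points).
Default geometry: each segment ramps 3.0 transformed-intensity units —
a clean lineage marker turning on over an arcsinh-scale range — against
noise 0.1; sibling directions are orthogonal to the parent's
and mutually spread (pairwise correlation −1/(k−1)), because diverging
lineages move into different marker programs.  That spread also makes
the generating topology recoverable from geometry alone: sibling arms
are farther from each other than from the trunk, so the zero-noise MST
over segment means reproduces the tree exactly.

`simulate_samples_over_time` emulates a directed-differentiation time
course: sample *t* draws positions from a Gaussian (sd 0.15, clipped to
[0, 1]) centred proportionally to `t · drift`, so later time points sit
further along a single program; `drift = 0` makes time points
exchangeable.

What the generator does *not* emulate: spillover artefacts, doublets,
debris, dead cells, batch effects, non-linear (sigmoidal or transient)
marker dynamics, or correlated noise.  Passing tests therefore show the
algorithms are implemented correctly and recover structure under clean
branching ramps; they do not certify performance on instrument
artefacts or subtle real-data topologies.  Batch correction is a hook
(`EventMatrix.replace_values`) for matrices corrected externally.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by design:
oracle checks use graphs of ≤ 60 nodes (against a hand-written
Floyd–Warshall), centroid sets of ≤ 6 clusters (against exhaustive
spanning-tree enumeration), and recovery runs of 800–3,600 cells —
sizes at which exact enumeration is feasible and the full pipeline
completes in seconds.  Every stochastic step (SOM, k-means, UMAP/tSNE,
downsampling, merging, Louvain) takes an explicit seed; identical seeds
give identical results, and the pipeline writes byte-identical
`pseudotime.csv` and `tree.json` across reruns.

## Known limitations

- Pseudotime is a single global field; branch-specific alignment and
  probabilistic (diffusion-type) pseudotime are out of scope.
- The MST backbone assumes the process is tree-shaped; cyclic or
  convergent differentiation will be forced into a tree.
- One shortest path is walked per (root, leaf, direction) triple; cells
  on co-optimal paths not selected by the tie-break receive no count.
- The FCS reader handles single-dataset FCS 3.0/3.1 list-mode files
  only; FCS writing is limited to the float32 fixture dialect.
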