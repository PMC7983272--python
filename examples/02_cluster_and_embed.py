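"""Cluster cells with a SOM, downsample per cluster and embed.

Simulates a three-armed differentiation tree, clusters all cells on the
default 6x6 SOM grid, keeps 30% of each cluster (small clusters always
survive), and computes PCA and diffusion-map embeddings of the kept cells.
"""

import numpy as np

import cytotrail as ct

matrix, truth = ct.simulate_tree_data(
    ct.star3_topology(), n_per_segment=200, n_markers=10, noise_sd=0.1, seed=7
)
state = ct.create_state(matrix)

ct.run_cluster(state, method="som", seed=7)         # 6x6 grid by default
table = ct.cluster_coordinates(state)               # per-cluster mean expression
print(f"clusters: {len(table.cluster_ids)}, sizes "
      f"min={table.sizes.min()} median={int(np.median(table.sizes))} max={table.sizes.max()}")

ct.cluster_downsample(state, fraction=0.3, seed=7)
print(f"kept after per-cluster downsampling: {int(state.kept_mask.sum())} "
      f"of {state.n_cells} cells")

ct.run_dimred(state, method="pca", ndim=2, seed=7)
ct.run_dimred(state, method="dm", ndim=2, seed=7)
pca = state.embeddings["pca"]
print(f"PCA coordinates: {pca.shape}, first component range "
      f"[{pca[:, 0].min():.2f}, {pca[:, 0].max():.2f}]")
# on branching data the first components separate the arms; the cluster
# centroids in either space can serve as trajectory coordinates
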