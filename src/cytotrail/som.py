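"""Online self-organizing map on a rectangular grid.

The SOM places ``xdim * ydim`` prototype vectors on a 2-D grid and trains
them competitively: each presented cell moves its nearest (Euclidean)
prototype and, early in training, the prototypes of neighbouring grid
nodes as well.  Cells are then assigned to the grid node whose prototype
is nearest — the standard cytometry clustering step popularised by
FlowSOM-style workflows.

Training schedule: ``rlen`` passes over the data in seeded random order;
the learning rate decays linearly between ``alpha[0]`` and ``alpha[1]``
and the Gaussian neighbourhood radius decays linearly from half the grid
diagonal to 0.5 (by the end only the winner moves appreciably).

Dead-unit handling: a prototype that wins no cell can never update once
the neighbourhood has shrunk, wasting map capacity on multimodal data.
After training, dead prototypes are re-seeded on the cells with the
largest quantisation error and refined with a few winner-mean updates —
the same empty-cluster policy k-means implementations use — so every
map node describes part of the data whenever the data has at least as
many modes as the grid has nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SOMResult:
    weights: np.ndarray        # (xdim * ydim) x n_features prototypes
    grid: np.ndarray           # (xdim * ydim) x 2 node coordinates
    labels: np.ndarray         # per-cell winning node index, 0-based
    xdim: int
    ydim: int


def _winners(data: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # squared Euclidean winner search; chunked to bound memory
    out = np.empty(data.shape[0], dtype=np.int64)
    step = max(1, 2_000_000 // max(1, weights.shape[0]))
    w2 = (weights ** 2).sum(axis=1)
    for lo in range(0, data.shape[0], step):
        chunk = data[lo : lo + step]
        d2 = w2[None, :] - 2.0 * chunk @ weights.T
        out[lo : lo + step] = np.argmin(d2, axis=1)
    return out


def som_fit(
    matrix: np.ndarray,
    xdim: int = 6,
    ydim: int = 6,
    rlen: int = 8,
    alpha: tuple[float, float] = (0.05, 0.01),
    seed: int = 0,
) -> SOMResult:
    """Train a SOM and assign each row to its winning node.

    Parameters
    ----------
    matrix : ndarray (cells x features)
        Finite expression values.
    xdim, ydim : int
        Grid dimensions; ``xdim * ydim`` is the maximum cluster count.
    rlen : int
        Passes over the data.
    alpha : (float, float)
        Start and end learning rate (linear decay).
    seed : int
        Seeds prototype initialisation and presentation order; identical
        seeds give identical assignments.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite values")
    if xdim < 1 or ydim < 1 or xdim * ydim < 2:
        raise ValueError("grid must contain at least 2 nodes")

    n, _ = matrix.shape
    n_nodes = xdim * ydim
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(xdim), np.arange(ydim), indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)

    # initialise prototypes on sampled data rows (with replacement if few)
    init_rows = rng.choice(n, size=n_nodes, replace=n < n_nodes)
    weights = matrix[init_rows].astype(float).copy()

    total = rlen * n
    if total > 0:
        order = np.concatenate([rng.permutation(n) for _ in range(rlen)])
        radius0 = max(np.hypot(xdim - 1, ydim - 1) / 2.0, 0.5)
        grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=-1)
        # per-step schedules; the radius decays to (almost) zero so the last
        # stretch of training is winner-only and prototypes settle on local means
        frac = np.arange(total) / total
        alphas = alpha[0] + (alpha[1] - alpha[0]) * frac
        radii = np.maximum(radius0 * (1.0 - frac), 0.05)
        for step, row in enumerate(order):
            x = matrix[row]
            diff = weights - x
            bmu = int(np.argmin((diff ** 2).sum(axis=1)))
            influence = np.exp(-grid_d2[bmu] / (2.0 * radii[step] ** 2))
            weights -= (alphas[step] * influence)[:, None] * diff

    if total > 0:
        weights = _reseed_dead_units(matrix, weights)
    labels = _winners(matrix, weights)
    return SOMResult(weights=weights, grid=grid, labels=labels, xdim=xdim, ydim=ydim)


def _reseed_dead_units(
    matrix: np.ndarray, weights: np.ndarray, max_rounds: int = 5
) -> np.ndarray:
    """Re-seed prototypes that win no cell onto the worst-quantised cells.

    Each round assigns cells to winners, plants every dead prototype on a
    distinct cell of maximal quantisation error, then applies two
    winner-mean (Lloyd) refinement steps.  Deterministic; stops as soon
    as every prototype wins at least one cell.
    """
    n_nodes = weights.shape[0]
    if matrix.shape[0] < n_nodes:
        return weights
    for _ in range(max_rounds):
        labels = _winners(matrix, weights)
        used = np.unique(labels)
        if used.size == n_nodes:
            break
        dead = np.setdiff1d(np.arange(n_nodes), used)
        err = ((matrix - weights[labels]) ** 2).sum(axis=1)
        worst = np.argsort(err)[::-1]
        for node, row in zip(dead, worst):
            weights[node] = matrix[row]
        for _ in range(2):
            labels = _winners(matrix, weights)
            for node in range(n_nodes):
                members = labels == node
                if members.any():
                    weights[node] = matrix[members].mean(axis=0)
    return weights
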