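"""Synthetic branching differentiation data with known ground truth.

Cells are sampled along a rooted tree of *segments*.  Each segment
carries a linear marker program: a start and an end mean vector, with a
child segment starting exactly where its parent ended (continuity at
branch points).  A cell drawn at position ``u`` in [0, 1) along segment
``s`` has mean ``(1 - u) * start_s + u * end_s`` plus independent
Gaussian noise, and its true pseudotime is its depth along the
root-to-cell path scaled to [0, 1].

This emulates multi-branch differentiation time courses — gradual,
roughly monotone marker ramps per lineage — while remaining simple
enough that recovery of the topology and pseudotime can be asserted
exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from cytotrail.io import write_fcs
from cytotrail.model import EventMatrix

#: default ramp length per segment in transformed-intensity units; a shift
#: of ~3 over a segment with noise_sd ~0.1 resembles a clean lineage marker
#: turning on over an arcsinh-scale range.
DEFAULT_RAMP_LENGTH = 3.0


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    topology: list[tuple[Optional[int], int]]  # (parent, child) segment ids
    segment: np.ndarray                        # per-cell segment id
    position: np.ndarray                       # per-cell u in [0, 1) within segment
    pseudotime: np.ndarray                     # per-cell true pseudotime in [0, 1]
    programs: dict                             # segment -> (start, end) mean vectors
    noise_sd: float
    seed: int

    def root_segment(self) -> int:
        children = {c for p, c in self.topology if p is not None}
        roots = [c for p, c in self.topology if p is None]
        if roots:
            return roots[0]
        all_segs = {c for _, c in self.topology} | {p for p, _ in self.topology if p is not None}
        orphans = sorted(all_segs - children)
        return orphans[0]

    def path_to_root(self, segment: int) -> list[int]:
        parent = {c: p for p, c in self.topology}
        path = [segment]
        while parent.get(path[-1]) is not None:
            path.append(parent[path[-1]])
        return path[::-1]


def star3_topology() -> list[tuple[Optional[int], int]]:
    """A root segment with three diverging arms — the canonical multi-branch
    differentiation shape (one progenitor pool, three terminal fates)."""
    return [(None, 0), (0, 1), (0, 2), (0, 3)]


def _check_tree(topology: Sequence[tuple[Optional[int], int]]) -> dict[int, Optional[int]]:
    parent: dict[int, Optional[int]] = {}
    for p, c in topology:
        if c in parent:
            raise ValueError(f"segment {c} listed twice")
        parent[c] = p
    for c in parent:
        seen = {c}
        node = parent.get(c)
        while node is not None:
            if node in seen:
                raise ValueError("topology contains a cycle")
            seen.add(node)
            node = parent.get(node)
    roots = [c for c, p in parent.items() if p is None or p not in parent]
    if len([c for c, p in parent.items() if p is None]) != 1:
        raise ValueError("topology must have exactly one root segment (parent None)")
    del roots
    return parent


def _default_programs(
    order: list[int],
    parent: dict[int, Optional[int]],
    n_markers: int,
    ramp_length: float,
    rng: np.random.Generator,
) -> dict:
    """Random linear programs whose branches genuinely diverge.

    Each segment ramps ``ramp_length`` along a unit direction.  Sibling
    segments get directions orthogonal to their parent's and mutually
    spread (centred, so pairwise negatively correlated) — lineages leaving
    a branch point move into different marker programs, which keeps
    sibling arms farther apart than each arm is from the trunk and makes
    the generating topology recoverable from the data geometry.
    """
    direction: dict[int, np.ndarray] = {}
    children: dict[Optional[int], list[int]] = {}
    for seg in order:
        children.setdefault(parent[seg], []).append(seg)
    for par, sibs in children.items():
        raw = []
        for _ in sibs:
            v = rng.normal(size=n_markers)
            if par is not None:
                p = direction[par]
                v = v - (v @ p) * p
            raw.append(v / np.linalg.norm(v))
        if len(sibs) > 1 and n_markers > len(sibs):
            # orthonormalise then centre: siblings end up pairwise
            # negatively correlated (cos = -1/(k-1)), evenly spread
            q, _ = np.linalg.qr(np.column_stack(raw))
            basis = [q[:, i] * np.sign(q[:, i] @ raw[i]) for i in range(len(sibs))]
            center = np.mean(basis, axis=0)
            raw = [v - center for v in basis]
        elif len(sibs) > 1:
            center = np.mean(raw, axis=0)
            raw = [v - center for v in raw]
        for seg, v in zip(sibs, raw):
            direction[seg] = v / np.linalg.norm(v)
    programs: dict = {}
    for seg in order:
        start = np.zeros(n_markers) if parent[seg] is None else programs[parent[seg]][1]
        programs[seg] = (start, start + ramp_length * direction[seg])
    return programs


def simulate_tree_data(
    topology: Sequence[tuple[Optional[int], int]],
    n_per_segment: int = 200,
    n_markers: int = 10,
    noise_sd: float = 0.1,
    seed: int = 7,
    programs: Optional[dict] = None,
    ramp_length: float = DEFAULT_RAMP_LENGTH,
) -> tuple[EventMatrix, SyntheticTruth]:
    """Sample cells along a segment tree with linear marker programs.

    Parameters
    ----------
    topology : list of (parent, child)
        Rooted segment tree; the root has parent ``None``.
    n_per_segment : int
        Cells drawn uniformly along each segment.
    n_markers : int
        Marker count (>= 2).
    noise_sd : float
        SD of independent Gaussian noise added per marker.
    seed : int
        Seeds program directions, positions and noise; same seed, same data.
    programs : dict, optional
        Explicit ``{segment: (start, end)}`` mean vectors; by default the
        root starts at the origin and each segment ramps a distance of
        ``ramp_length`` in a random direction, children continuing from
        their parent's end point.
    """
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    parent = _check_tree(topology)
    rng = np.random.default_rng(seed)

    order: list[int] = []  # parents before children
    remaining = set(parent)
    while remaining:
        progressed = False
        for c in sorted(remaining):
            if parent[c] is None or parent[c] not in remaining:
                order.append(c)
                remaining.discard(c)
                progressed = True
        if not progressed:
            raise ValueError("topology is not a rooted tree")

    if programs is None:
        programs = _default_programs(order, parent, n_markers, ramp_length, rng)
    else:
        programs = {s: (np.asarray(a, float), np.asarray(b, float)) for s, (a, b) in programs.items()}

    depth = {}
    for seg in order:
        depth[seg] = 0 if parent[seg] is None else depth[parent[seg]] + 1
    max_depth = max(depth.values()) + 1  # path length in segments

    segments, positions, rows = [], [], []
    for seg in order:
        start, end = programs[seg]
        u = rng.uniform(size=n_per_segment)
        means = (1 - u)[:, None] * start[None, :] + u[:, None] * end[None, :]
        noise = rng.normal(scale=noise_sd, size=means.shape) if noise_sd > 0 else 0.0
        rows.append(means + noise)
        segments.append(np.full(n_per_segment, seg))
        positions.append(u)

    values = np.vstack(rows)
    segment_arr = np.concatenate(segments)
    position_arr = np.concatenate(positions)
    true_pt = np.array(
        [(depth[s] + u) / max_depth for s, u in zip(segment_arr, position_arr)]
    )

    n = values.shape[0]
    matrix = EventMatrix(
        values,
        [f"M{j + 1}" for j in range(n_markers)],
        [f"c{i:05d}" for i in range(n)],
        [f"seg{int(s)}" for s in segment_arr],
    )
    truth = SyntheticTruth(
        topology=list(topology),
        segment=segment_arr.astype(int),
        position=position_arr,
        pseudotime=true_pt,
        programs=programs,
        noise_sd=noise_sd,
        seed=seed,
    )
    return matrix, truth


def simulate_samples_over_time(
    n_timepoints: int = 5,
    drift: float = 1.0,
    n_per_timepoint: int = 500,
    n_markers: int = 10,
    noise_sd: float = 0.1,
    seed: int = 0,
    ramp_length: float = DEFAULT_RAMP_LENGTH,
) -> list[EventMatrix]:
    """Per-timepoint samples drifting along a single linear program.

    Sample ``t`` draws positions from a Gaussian centred at
    ``t * drift / (n_timepoints - 1)`` (sd 0.15, clipped to [0, 1]), so
    with positive drift later samples sit further along the program —
    the shape of a directed differentiation time course.  ``drift = 0``
    makes all time points exchangeable.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=n_markers)
    direction /= np.linalg.norm(direction)
    start = np.zeros(n_markers)
    end = ramp_length * direction

    samples = []
    for t in range(n_timepoints):
        center = drift * t / (n_timepoints - 1)
        u = np.clip(rng.normal(loc=center, scale=0.15, size=n_per_timepoint), 0, 1)
        means = (1 - u)[:, None] * start[None, :] + u[:, None] * end[None, :]
        noise = rng.normal(scale=noise_sd, size=means.shape) if noise_sd > 0 else 0.0
        samples.append(
            EventMatrix(
                means + noise,
                [f"M{j + 1}" for j in range(n_markers)],
                [f"t{t}_{i:05d}" for i in range(n_per_timepoint)],
                [f"D{t}"] * n_per_timepoint,
            )
        )
    return samples


def write_fixture_fcs(matrix: EventMatrix, path, spillover=None) -> None:
    """Write an :class:`EventMatrix` as a minimal valid FCS 3.1 file."""
    if matrix.n_cells > 100_000:
        raise ValueError("fixture FCS writer is capped at 100,000 cells")
    write_fcs(
        path,
        matrix.values,
        channel_names=matrix.markers,
        marker_names=matrix.markers,
        spillover=spillover,
    )
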