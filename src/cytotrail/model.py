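"""Workflow state container.

``EventMatrix`` is the cells x markers expression matrix with per-cell
identifiers and sample (stage / time point) labels.  ``CytoState`` carries
that matrix together with every downstream result — cluster labels, the
cluster-dependent downsampling mask, embeddings, the centroid table, the
trajectory tree, the KNN cell graph, pseudotime, root/leaf flags and walk
counts — plus an append-only log of the steps that produced them.

Stage order is enforced: re-running an upstream stage clears everything
downstream of it, so a state can never hold a tree built from stale
cluster labels or a pseudotime field computed on a replaced graph.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd


@dataclass
class EventMatrix:
    """Cells x markers matrix of (typically transformed) intensities.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_markers)
        Expression values; must be finite.
    markers : list of str
        Unique marker names, one per column.
    cell_ids : list of str
        Unique per-cell identifiers.
    sample_labels : list of str
        Per-cell sample / stage / time-point label.
    """

    values: np.ndarray
    markers: list[str]
    cell_ids: list[str]
    sample_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one cell and one marker")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        self.markers = [str(x) for x in self.markers]
        self.cell_ids = [str(x) for x in self.cell_ids]
        self.sample_labels = [str(x) for x in self.sample_labels]
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker names for {m} columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.sample_labels) != n:
            raise ValueError(f"{len(self.sample_labels)} sample labels for {n} rows")
        if len(set(self.markers)) != m:
            raise ValueError("marker names must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def select_markers(self, markers: list[str]) -> "EventMatrix":
        """Return a copy restricted to ``markers`` (in the given order)."""
        missing = [m for m in markers if m not in self.markers]
        if missing:
            raise KeyError(f"unknown markers: {missing}")
        idx = [self.markers.index(m) for m in markers]
        return EventMatrix(
            self.values[:, idx].copy(),
            list(markers),
            list(self.cell_ids),
            list(self.sample_labels),
        )

    def subset_cells(self, row_index: np.ndarray) -> "EventMatrix":
        """Return a copy restricted to the rows in ``row_index``."""
        row_index = np.asarray(row_index)
        if row_index.dtype == bool:
            row_index = np.flatnonzero(row_index)
        return EventMatrix(
            self.values[row_index],
            list(self.markers),
            [self.cell_ids[i] for i in row_index],
            [self.sample_labels[i] for i in row_index],
        )

    def replace_values(self, values: np.ndarray) -> "EventMatrix":
        """Swap in an externally corrected matrix of the same shape.

        Hook for batch correction performed outside the package (e.g. an
        empirical-Bayes correction across time points): the corrected matrix
        keeps the original cell ids, labels and marker names.
        """
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError(f"shape {values.shape} != {self.values.shape}")
        return EventMatrix(values, list(self.markers), list(self.cell_ids), list(self.sample_labels))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.markers)


# Downstream-invalidation order.  Re-running a stage clears every field of
# every later stage that depends on it.
_STAGE_FIELDS = {
    "cluster": ["cluster_labels", "kept_mask", "cluster_table", "tree", "cell_graph",
                "pseudotime", "distances", "root_flags", "leaf_flags", "walk"],
    "downsample": ["kept_mask", "cell_graph", "pseudotime", "distances",
                   "root_flags", "leaf_flags", "walk"],
    "tree": ["tree"],
    "graph": ["cell_graph", "pseudotime", "distances", "root_flags", "leaf_flags", "walk"],
    "roots": ["root_flags", "pseudotime", "distances", "leaf_flags", "walk"],
    "pseudotime": ["pseudotime", "distances", "leaf_flags", "walk"],
    "leaves": ["leaf_flags", "walk"],
    "walk": ["walk"],
}


@dataclass
class CytoState:
    """Container for the full trajectory workflow over one merged dataset."""

    matrix: EventMatrix
    cluster_labels: Optional[np.ndarray] = None      # per-cell, 1..K
    kept_mask: Optional[np.ndarray] = None           # per-cell bool
    embeddings: dict = field(default_factory=dict)   # name -> per-cell (kept) coords
    cluster_table: Any = None                        # ClusterTable
    tree: Any = None                                 # TrajectoryTree
    cell_graph: Any = None                           # CellGraph
    pseudotime: Optional[np.ndarray] = None          # per-cell in [0, 1]
    distances: Optional[np.ndarray] = None           # per-cell mean distance to roots
    root_flags: Optional[np.ndarray] = None
    leaf_flags: Optional[np.ndarray] = None
    walk: Any = None                                 # WalkResult
    log: list = field(default_factory=list)

    # -- bookkeeping -------------------------------------------------------

    def record(self, step: str, **params: Any) -> None:
        """Append a log entry; the log only ever grows."""
        self.log.append(
            {
                "step": step,
                "params": params,
                "time": datetime.datetime.now().isoformat(timespec="seconds"),
            }
        )

    def invalidate(self, stage: str) -> None:
        """Clear every result downstream of ``stage`` (inclusive)."""
        for name in _STAGE_FIELDS[stage]:
            if name == "kept_mask":
                self.kept_mask = None
            else:
                setattr(self, name, None)
        if stage == "cluster":
            self.embeddings = {}

    def require(self, field_name: str, needed_for: str) -> Any:
        value = getattr(self, field_name)
        if value is None or (field_name == "embeddings" and not value):
            raise RuntimeError(
                f"{needed_for} requires '{field_name}' but it has not been computed; "
                f"run the earlier workflow stage first"
            )
        return value

    # -- derived views -----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def kept_indices(self) -> np.ndarray:
        """Row indices of cells surviving downsampling (all cells if none)."""
        if self.kept_mask is None:
            return np.arange(self.n_cells)
        return np.flatnonzero(self.kept_mask)

    def check_invariants(self) -> None:
        n = self.n_cells
        for name in ("cluster_labels", "kept_mask", "pseudotime", "root_flags", "leaf_flags"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise AssertionError(f"{name} has length {len(v)} != {n} cells")
        if self.pseudotime is not None:
            pt = self.pseudotime[~np.isnan(self.pseudotime)]
            if pt.size and (pt.min() < -1e-12 or pt.max() > 1 + 1e-12):
                raise AssertionError("pseudotime outside [0, 1]")
            if self.root_flags is not None:
                roots = self.root_flags & ~np.isnan(self.pseudotime)
                if np.any(self.pseudotime[roots] != 0):
                    raise AssertionError("root cell with nonzero pseudotime")
        if self.root_flags is not None and self.leaf_flags is not None:
            if np.any(self.root_flags & self.leaf_flags):
                raise AssertionError("a cell is flagged both root and leaf")


def create_state(matrix: EventMatrix, markers: Optional[list[str]] = None) -> CytoState:
    """Build a fresh workflow state from a merged matrix.

    Parameters
    ----------
    matrix : EventMatrix
        The merged, preprocessed expression matrix.
    markers : list of str, optional
        Markers to analyse; defaults to all.  Unknown names raise ``KeyError``.
    """
    if matrix.n_cells < 2:
        raise ValueError("a trajectory needs at least 2 cells")
    if markers is not None:
        matrix = matrix.select_markers(markers)
    state = CytoState(matrix=matrix)
    state.record("create_state", n_cells=matrix.n_cells, markers=list(matrix.markers))
    return state


def summarize(state: CytoState) -> str:
    """Human-readable report of what the state contains."""
    m = state.matrix
    lines = [
        f"CytoState: {m.n_cells} cells x {m.n_markers} markers",
        f"  samples: {sorted(set(m.sample_labels))}",
    ]
    if state.cluster_labels is not None:
        lines.append(f"  clusters: {len(np.unique(state.cluster_labels))}")
    else:
        lines.append("  clusters: (not run)")
    if state.kept_mask is not None:
        lines.append(f"  downsampled: {int(state.kept_mask.sum())} cells kept")
    lines.append(
        f"  embeddings: {sorted(state.embeddings)}" if state.embeddings else "  embeddings: (none)"
    )
    lines.append(f"  tree: {'built' if state.tree is not None else '(not built)'}")
    lines.append(f"  cell graph: {'built' if state.cell_graph is not None else '(not built)'}")
    if state.pseudotime is not None:
        valid = state.pseudotime[~np.isnan(state.pseudotime)]
        lines.append(f"  pseudotime: range [{valid.min():.3f}, {valid.max():.3f}]")
    else:
        lines.append("  pseudotime: (not run)")
    lines.append(f"  walk: {'scored' if state.walk is not None else '(not run)'}")
    lines.append(f"  log: {len(state.log)} steps")
    for entry in state.log:
        lines.append(f"    - {entry['step']} {entry['params']}")
    return "\n".join(lines)


# -- persistence -----------------------------------------------------------


def _opt_col(values: Optional[np.ndarray]) -> list:
    if values is None:
        return []
    return np.asarray(values).tolist()


def save_state(state: CytoState, out_dir: str) -> None:
    """Serialize a state to a directory of CSV/JSON files."""
    os.makedirs(out_dir, exist_ok=True)
    state.matrix.to_dataframe().to_csv(os.path.join(out_dir, "matrix.csv"))
    meta = pd.DataFrame(
        {"cell_id": state.matrix.cell_ids, "sample": state.matrix.sample_labels}
    )
    meta.to_csv(os.path.join(out_dir, "meta.csv"), index=False)

    if state.cluster_labels is not None:
        cols = {"cell_id": state.matrix.cell_ids,
                "cluster": state.cluster_labels.astype(int)}
        if state.kept_mask is not None:
            cols["kept"] = state.kept_mask.astype(int)
        pd.DataFrame(cols).to_csv(os.path.join(out_dir, "clusters.csv"), index=False)

    if state.embeddings:
        emb_dir = os.path.join(out_dir, "embeddings")
        os.makedirs(emb_dir, exist_ok=True)
        kept = state.kept_indices()
        ids = [state.matrix.cell_ids[i] for i in kept]
        for name, coords in state.embeddings.items():
            df = pd.DataFrame(coords, index=ids)
            df.index.name = "cell_id"
            df.to_csv(os.path.join(emb_dir, f"{name}.csv"))

    if state.tree is not None:
        with open(os.path.join(out_dir, "tree.json"), "w") as fh:
            json.dump(state.tree.to_dict(), fh, indent=1)
    if state.cell_graph is not None:
        with open(os.path.join(out_dir, "graph.json"), "w") as fh:
            json.dump(state.cell_graph.to_dict(), fh)

    if state.pseudotime is not None:
        counts = state.walk.counts if state.walk is not None else np.zeros(state.n_cells, int)
        inter = state.walk.intermediate if state.walk is not None else np.zeros(state.n_cells, bool)
        df = pd.DataFrame(
            {
                "cell_id": state.matrix.cell_ids,
                "D_i": state.distances,
                "pseudotime": state.pseudotime,
                "is_root": _opt_col(state.root_flags) or [False] * state.n_cells,
                "is_leaf": _opt_col(state.leaf_flags) or [False] * state.n_cells,
                "walk_count": counts,
                "is_intermediate": inter,
            }
        )
        df.to_csv(os.path.join(out_dir, "pseudotime.csv"), index=False)

    with open(os.path.join(out_dir, "log.json"), "w") as fh:
        json.dump(state.log, fh, indent=1)


def load_state(out_dir: str) -> CytoState:
    """Rebuild a state from :func:`save_state` output.

    Embeddings, cluster labels, tree, graph, pseudotime and log are restored;
    the walk result is restored from pseudotime.csv counts.
    """
    from cytotrail.pseudotime import CellGraph, WalkResult
    from cytotrail.tree import TrajectoryTree

    mat = pd.read_csv(os.path.join(out_dir, "matrix.csv"), index_col=0)
    meta = pd.read_csv(os.path.join(out_dir, "meta.csv"), dtype=str)
    matrix = EventMatrix(
        mat.to_numpy(float),
        list(mat.columns),
        [str(i) for i in mat.index],
        list(meta["sample"]),
    )
    state = CytoState(matrix=matrix)

    cpath = os.path.join(out_dir, "clusters.csv")
    if os.path.exists(cpath):
        cdf = pd.read_csv(cpath)
        state.cluster_labels = cdf["cluster"].to_numpy(int)
        if "kept" in cdf.columns:
            state.kept_mask = cdf["kept"].to_numpy(bool)

    emb_dir = os.path.join(out_dir, "embeddings")
    if os.path.isdir(emb_dir):
        for fname in sorted(os.listdir(emb_dir)):
            name = fname[: -len(".csv")]
            df = pd.read_csv(os.path.join(emb_dir, fname), index_col=0)
            state.embeddings[name] = df.to_numpy(float)

    tpath = os.path.join(out_dir, "tree.json")
    if os.path.exists(tpath):
        with open(tpath) as fh:
            state.tree = TrajectoryTree.from_dict(json.load(fh))
    gpath = os.path.join(out_dir, "graph.json")
    if os.path.exists(gpath):
        with open(gpath) as fh:
            state.cell_graph = CellGraph.from_dict(json.load(fh))

    ppath = os.path.join(out_dir, "pseudotime.csv")
    if os.path.exists(ppath):
        pdf = pd.read_csv(ppath)
        state.distances = pdf["D_i"].to_numpy(float)
        state.pseudotime = pdf["pseudotime"].to_numpy(float)
        state.root_flags = pdf["is_root"].to_numpy(bool)
        state.leaf_flags = pdf["is_leaf"].to_numpy(bool)
        counts = pdf["walk_count"].to_numpy(int)
        if counts.any():
            state.walk = WalkResult(
                counts=counts,
                intermediate=pdf["is_intermediate"].to_numpy(bool),
                params={},
                skipped_pairs=[],
            )

    lpath = os.path.join(out_dir, "log.json")
    if os.path.exists(lpath):
        with open(lpath) as fh:
            state.log = json.load(fh)
    return state
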