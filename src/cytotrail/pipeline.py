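"""End-to-end pipeline with a persisted state directory and resume logic.

``run_pipeline`` chains preprocess -> cluster -> (downsample) -> dimred
-> tree -> branches -> knn -> roots -> pseudotime -> leaves -> walk.
Dimensionality reduction, downsampling and the walk are optional stages.
The stage parameters of the last run are stored beside the state; a
rerun with a changed configuration resumes from the first stage whose
parameters (or whose upstream) changed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cytotrail import cluster as _cluster
from cytotrail import io as _io
from cytotrail import pseudotime as _pt
from cytotrail import tree as _tree
from cytotrail.model import CytoState, EventMatrix, create_state, load_state, save_state

_KNOWN_KEYS = {
    "transform", "cofactor", "gates", "compensate", "n_per_sample",
    "cluster_method", "xdim", "ydim", "rlen", "k_clusters",
    "downsample_fraction", "dimred_methods", "ndim",
    "tree_space", "branch_resolution",
    "knn_k", "knn_space", "root_clusters", "root_cells",
    "leaf_clusters", "leaf_cells", "leaf_quantile", "walk_quantile",
    "run_walk", "seed",
}


@dataclass
class RunConfig:
    """All stage parameters with their defaults; unknown keys are rejected."""

    transform: str = "arcsinh"
    cofactor: float = 5.0
    gates: list = field(default_factory=list)        # ["CD34:0:inf", ...]
    compensate: str = "auto"
    n_per_sample: int = 2000
    cluster_method: str = "som"
    xdim: int = 6
    ydim: int = 6
    rlen: int = 8
    k_clusters: Optional[int] = None
    downsample_fraction: Optional[float] = None
    dimred_methods: list = field(default_factory=list)   # e.g. ["pca", "umap"]
    ndim: int = 2
    tree_space: str = "expression"
    branch_resolution: float = 1.0
    knn_k: Optional[int] = None                      # None = ceil(sqrt(n)) cap 30
    knn_space: str = "expression"
    root_clusters: list = field(default_factory=list)
    root_cells: list = field(default_factory=list)
    leaf_clusters: list = field(default_factory=list)
    leaf_cells: list = field(default_factory=list)
    leaf_quantile: Optional[float] = 0.02
    walk_quantile: float = 0.8
    run_walk: bool = True
    seed: int = 42

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            if str(path).endswith(".toml"):
                import tomllib

                return cls.from_dict(tomllib.load(fh))
            return cls.from_dict(json.load(fh))

    def stage_params(self) -> dict[str, dict]:
        """Per-stage parameter dicts used for resume comparison."""
        d = asdict(self)
        return {
            "preprocess": {k: d[k] for k in
                           ("transform", "cofactor", "gates", "compensate",
                            "n_per_sample", "seed")},
            "cluster": {k: d[k] for k in
                        ("cluster_method", "xdim", "ydim", "rlen", "k_clusters", "seed")},
            "downsample": {"fraction": d["downsample_fraction"], "seed": d["seed"]},
            "dimred": {k: d[k] for k in ("dimred_methods", "ndim", "seed")},
            "tree": {"space": d["tree_space"]},
            "branches": {"resolution": d["branch_resolution"], "seed": d["seed"]},
            "knn": {"k": d["knn_k"], "space": d["knn_space"]},
            "roots": {"clusters": d["root_clusters"], "cells": d["root_cells"]},
            "pseudotime": {},
            "leaves": {k: d[k] for k in ("leaf_clusters", "leaf_cells", "leaf_quantile")},
            "walk": {"quantile": d["walk_quantile"], "enabled": d["run_walk"]},
        }


_STAGE_ORDER = [
    "preprocess", "cluster", "downsample", "dimred", "tree", "branches",
    "knn", "roots", "pseudotime", "leaves", "walk",
]


def _parse_gate(text: str) -> _io.GateSpec:
    channel, lo, hi = text.split(":")
    lo_v = -np.inf if lo in ("-inf", "") else float(lo)
    hi_v = np.inf if hi in ("inf", "") else float(hi)
    return _io.GateSpec(channel, lo_v, hi_v)


def _load_inputs(config: RunConfig, input_paths: Sequence[str]) -> EventMatrix:
    gates = [_parse_gate(g) for g in config.gates]
    fcs = [p for p in input_paths if str(p).lower().endswith(".fcs")]
    tables = [p for p in input_paths if not str(p).lower().endswith(".fcs")]
    samples: list[EventMatrix] = []
    if fcs:
        merged = _io.preprocess_fcs(
            fcs,
            compensate_mode=config.compensate,
            gates=gates,
            method=config.transform,
            cofactor=config.cofactor,
            n_per_sample=config.n_per_sample,
            seed=config.seed,
        )
        samples.append(merged)
    for path in tables:
        em = _io.read_matrix(path)
        if gates:
            em = em.subset_cells(_io.apply_gates(em.values, em.markers, gates))
        em = em.replace_values(
            _io.transform(em.values, method=config.transform, cofactor=config.cofactor)
        )
        samples.append(em)
    if not samples:
        raise ValueError("no readable inputs")
    if len(samples) == 1:
        return samples[0]
    return _io.merge_samples(samples, n_per_sample=config.n_per_sample, seed=config.seed)


def _first_changed_stage(out_dir: str, params: dict[str, dict]) -> str:
    marker = os.path.join(out_dir, "stages.json")
    if not os.path.exists(marker):
        return _STAGE_ORDER[0]
    with open(marker) as fh:
        previous = json.load(fh)
    for stage in _STAGE_ORDER:
        if previous.get(stage) != params[stage]:
            return stage
    return "done"


def run_pipeline(
    config: RunConfig,
    input_paths: Sequence[str] = (),
    out_dir: str = "cytotrail_run",
    matrix: Optional[EventMatrix] = None,
) -> CytoState:
    """Run (or resume) the full workflow and persist the state directory.

    ``matrix`` bypasses file input (e.g. a simulated or batch-corrected
    matrix).  On failure the partial state is saved and the failing stage
    named.  Returns the final state.
    """
    params = config.stage_params()
    start = _first_changed_stage(out_dir, params)
    start_idx = len(_STAGE_ORDER) if start == "done" else _STAGE_ORDER.index(start)
    resumable = os.path.exists(os.path.join(out_dir, "matrix.csv"))

    if start_idx == 0 or not resumable:
        if matrix is None:
            matrix = _load_inputs(config, input_paths)
        state = create_state(matrix)
        start_idx = max(start_idx, 1)  # preprocess done
    else:
        state = load_state(out_dir)
        state.record("resume", from_stage=_STAGE_ORDER[min(start_idx, len(_STAGE_ORDER) - 1)])
        for stage in _STAGE_ORDER[:start_idx]:
            state.record("skip", stage=stage, reason="parameters unchanged")

    executed = "preprocess"
    try:
        for stage in _STAGE_ORDER[start_idx:]:
            executed = stage
            if stage == "preprocess":
                continue
            if stage == "cluster":
                _cluster.run_cluster(
                    state, method=config.cluster_method, seed=config.seed,
                    xdim=config.xdim, ydim=config.ydim, rlen=config.rlen,
                    k=config.k_clusters,
                )
            elif stage == "downsample":
                if config.downsample_fraction is not None:
                    _cluster.cluster_downsample(
                        state, fraction=config.downsample_fraction, seed=config.seed
                    )
            elif stage == "dimred":
                for method in config.dimred_methods:
                    _cluster.run_dimred(state, method=method, ndim=config.ndim, seed=config.seed)
            elif stage == "tree":
                _tree.build_tree(state, space=config.tree_space)
            elif stage == "branches":
                _tree.detect_branches(
                    state, resolution=config.branch_resolution, seed=config.seed
                )
            elif stage == "knn":
                _pt.build_knn(state, k=config.knn_k, space=config.knn_space)
            elif stage == "roots":
                if not config.root_clusters and not config.root_cells:
                    raise ValueError(
                        "pseudotime requires root cells: set root_clusters or root_cells "
                        "(CLI: --roots)"
                    )
                _pt.def_root_cells(
                    state,
                    cells=config.root_cells or None,
                    clusters=config.root_clusters or None,
                )
            elif stage == "pseudotime":
                _pt.run_pseudotime(state)
            elif stage == "leaves":
                if config.leaf_clusters or config.leaf_cells:
                    _pt.def_leaf_cells(
                        state,
                        cells=config.leaf_cells or None,
                        clusters=config.leaf_clusters or None,
                    )
                elif config.leaf_quantile is not None:
                    _pt.def_leaf_cells(state, auto_quantile=config.leaf_quantile)
            elif stage == "walk":
                if config.run_walk and state.leaf_flags is not None:
                    _pt.orient_graph(state)
                    _pt.run_walk(state, quantile=config.walk_quantile)
    except Exception as exc:
        save_state(state, out_dir)
        raise RuntimeError(f"pipeline failed at stage '{executed}': {exc}") from exc

    state.check_invariants()
    save_state(state, out_dir)
    export_tables(state, out_dir)
    with open(os.path.join(out_dir, "stages.json"), "w") as fh:
        json.dump(params, fh, indent=1)
    return state


def export_tables(state: CytoState, out_dir: str) -> None:
    """Write the tabular exports (markers.csv, centroids.csv) when available."""
    if state.tree is not None and state.tree.branch_labels is not None:
        try:
            results, _ = _tree.diff_markers(state)
        except ValueError:
            results = []
        if results:
            pd.DataFrame(
                [
                    {"branch": r.branch, "marker": r.marker, "effect": r.effect,
                     "statistic": r.statistic, "p_raw": r.p_raw, "p_adj": r.p_adj}
                    for r in results
                ]
            ).to_csv(os.path.join(out_dir, "markers.csv"), index=False)
    if state.cluster_table is not None:
        table = state.cluster_table
        df = pd.DataFrame(
            table.centroid_expression,
            index=pd.Index(table.cluster_ids, name="cluster"),
            columns=state.matrix.markers,
        )
        df.insert(0, "size", table.sizes)
        df.to_csv(os.path.join(out_dir, "centroids.csv"))
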