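"""End-to-end orchestration: load → graph → interactions → d-tuples → states.

Every stage writes its output table into the run directory so stages can
be re-run or injected individually; identical config + seed gives
byte-identical outputs. A manifest records the config, seeds and stage
timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import data_io
from .data_io import BinaryMatrix, ExpressionMatrix
from .dependency_graph import DependencyGraph, pc_skeleton, refine_score
from .dtuple_stats import DTupleConfig, dtuple_table, extract_dtuples
from .mfi_estimation import ScanConfig, run_interaction_scan, scan_table
from .state_inference import (
    CellByTupleMatrix,
    assign_states,
    cell_state_matrix,
    cluster_dtuples,
    modularity_cut,
    state_table,
)

log = logging.getLogger("mfistates")


@dataclass
class RunConfig:
    input_path: str = ""
    input_format: str = "csv"
    n_genes: int = 1000
    user_genes: Optional[str] = None  # path, one gene per line
    genes_to_one: Optional[str] = None
    exclusion: Optional[str] = None  # path, one boolean per line
    select_hvg: bool = True
    pc_alpha: float = 0.05
    max_cond: int = 3
    restarts: int = 2
    n_boot: int = 1000
    lambda_threshold: float = 0.05
    orders: tuple[int, ...] = (2, 3, 4, 5)
    extend_orders: tuple[int, ...] = ()
    fdr: float = 0.05
    min_log2fc: float = 3.0
    min_cells: int = 0
    linkage: str = "average"
    dice_override: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("pc_alpha", 0.0, 1.0),
            ("lambda_threshold", 0.0, 1.0),
            ("fdr", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        self.orders = tuple(self.orders)
        self.extend_orders = tuple(self.extend_orders)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["orders"] = list(self.orders)
        d["extend_orders"] = list(self.extend_orders)
        return d


def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


@dataclass
class RunResult:
    config: RunConfig
    matrix: ExpressionMatrix
    binary: BinaryMatrix
    graph: DependencyGraph
    interactions: list
    dtuples: list
    states: list = field(default_factory=list)
    modularity: float = np.nan
    cut_height: float = np.nan


def run_pipeline(
    config: RunConfig,
    outdir: str,
    matrix: Optional[ExpressionMatrix] = None,
) -> RunResult:
    """Execute all stages; write tables, dendrogram and manifest to `outdir`.

    A pre-loaded matrix may be passed instead of reading `config.input_path`
    (used by the simulation subcommand and the test-suite fixtures).
    Any stage failure aborts with the stage named, leaving partial outputs
    plus a FAILED marker in place.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        stage = "load"
        t0 = time.perf_counter()
        if matrix is None:
            matrix = data_io.load_expression(config.input_path, config.input_format)
        if config.exclusion:
            flags = [s.lower() in ("1", "true", "t", "yes") for s in _read_lines(config.exclusion)]
            matrix = data_io.apply_qc(matrix, exclude=flags)
        user_genes = _read_lines(config.user_genes) if config.user_genes else []
        if config.select_hvg and (config.n_genes < matrix.n_genes or user_genes):
            matrix = data_io.select_genes(matrix, config.n_genes, user_genes)
        binary = data_io.binarise(matrix)
        data_io.write_csv(matrix, str(out / "qc_expression.csv"))
        data_io.write_csv(binary, str(out / "qc_binarised.csv"))
        timings[stage] = time.perf_counter() - t0

        stage = "graph"
        t0 = time.perf_counter()
        graph = pc_skeleton(binary, alpha=config.pc_alpha, max_cond=config.max_cond)
        graph = refine_score(
            graph, binary, restarts=config.restarts, seed=config.seed
        )
        graph.to_tsv(str(out / "graph_edges.tsv"))
        timings[stage] = time.perf_counter() - t0

        stage = "interactions"
        t0 = time.perf_counter()
        genes_to_one = (
            tuple(_read_lines(config.genes_to_one)) if config.genes_to_one else ()
        )
        scan_cfg = ScanConfig(
            orders=config.orders,
            extend_orders=config.extend_orders,
            n_boot=config.n_boot,
            lambda_threshold=config.lambda_threshold,
            genes_to_one=genes_to_one,
            seed=config.seed,
        )
        interactions = run_interaction_scan(binary, graph, scan_cfg)
        itab = scan_table(interactions).sort_values(["order", "genes"], kind="stable")
        itab.to_csv(out / "interactions.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "dtuples"
        t0 = time.perf_counter()
        dcfg = DTupleConfig(
            fdr=config.fdr, min_log2fc=config.min_log2fc, min_cells=config.min_cells
        )
        dtuples = extract_dtuples(interactions, binary, dcfg)
        dtuples.sort(key=lambda dt: (dt.genes, dt.state))
        dtuple_table(dtuples).to_csv(out / "dtuples.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "states"
        t0 = time.perf_counter()
        states: list = []
        q = np.nan
        height = np.nan
        if dtuples:
            ctm = CellByTupleMatrix.from_dtuples(dtuples, binary)
            if ctm.n_tuples >= 2:
                dend = cluster_dtuples(ctm, linkage=config.linkage)
                labels, q, height = modularity_cut(
                    dend, ctm, override_height=config.dice_override
                )
                with open(out / "dendrogram.nwk", "w") as fh:
                    fh.write(dend.to_newick() + "\n")
            else:
                labels = np.zeros(ctm.n_tuples, dtype=int)
            states = assign_states(labels, ctm, cut_height=height)
            csm = cell_state_matrix(states, binary.cell_ids)
            csm.to_csv(out / "cell_states.tsv", sep="\t")
            counts = csm.sum(axis=1).rename("n_states")
            counts.to_csv(out / "cell_state_counts.tsv", sep="\t")
        state_table(states).to_csv(out / "states.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0

        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "seed": config.seed,
            "n_cells": matrix.n_cells,
            "n_genes": matrix.n_genes,
            "n_retained_interactions": sum(e.retained for e in interactions),
            "n_dtuples": len(dtuples),
            "n_states": len(states),
            "modularity": None if np.isnan(q) else float(q),
            "cut_height": None if np.isnan(height) else float(height),
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return RunResult(
            config=config,
            matrix=matrix,
            binary=binary,
            graph=graph,
            interactions=interactions,
            dtuples=dtuples,
            states=states,
            modularity=q,
            cut_height=height,
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
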