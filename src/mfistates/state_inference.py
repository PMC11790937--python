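"""Clustering d-tuples into multi-label cell states.

d-tuples that co-label the same cells are grouped by agglomerative
clustering of their boolean cell-membership vectors under the Dice
dissimilarity d(X,Y) = 1 − 2|X∧Y|/(|X|+|Y|) (not a metric: it fails the
triangle inequality). The dendrogram is cut, by default, at the height
that maximises Newman's weighted modularity of the induced partition on
the complete d-tuple graph weighted by Dice similarity (1 − d); ties go
to the smallest height, i.e. the finest partition. Each cluster defines a
state; a cell belongs to every state one of whose d-tuples it carries, so
states overlap — cells are multi-labelled by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .data_io import BinaryMatrix
from .dtuple_stats import DTuple, member_cell_mask


@dataclass
class CellByTupleMatrix:
    """Cells x d-tuples boolean matrix; column j marks DTuple j's member cells."""

    values: np.ndarray
    tuple_index: list[DTuple]
    cell_ids: list[str]

    @classmethod
    def from_dtuples(
        cls, dtuples: Sequence[DTuple], b: BinaryMatrix
    ) -> "CellByTupleMatrix":
        cols = []
        for dt in dtuples:
            mask = (
                dt.member_cells
                if dt.member_cells is not None
                else member_cell_mask(b, dt.genes, dt.state)
            )
            cols.append(np.asarray(mask, dtype=bool))
        values = (
            np.column_stack(cols) if cols else np.zeros((b.n_cells, 0), dtype=bool)
        )
        return cls(values=values, tuple_index=list(dtuples), cell_ids=list(b.cell_ids))

    @property
    def n_tuples(self) -> int:
        return self.values.shape[1]


@dataclass
class Dendrogram:
    """scipy linkage matrix plus leaf count; heights are Dice dissimilarities."""

    linkage: np.ndarray
    n_leaves: int

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, height: float) -> np.ndarray:
        """0-based cluster labels with all merges of height ≤ `height` applied."""
        if self.linkage.shape[0] == 0:
            return np.zeros(self.n_leaves, dtype=int)
        return sch.fcluster(self.linkage, t=height, criterion="distance") - 1

    def to_newick(self, labels: Optional[Sequence[str]] = None) -> str:
        labels = list(labels) if labels is not None else [
            f"d{i}" for i in range(self.n_leaves)
        ]
        tree = sch.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return labels[node.id]
            left, right = rec(node.left), rec(node.right)
            bl_l = node.dist - node.left.dist
            bl_r = node.dist - node.right.dist
            return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

        return rec(tree) + ";"


def dice_dissimilarity(x: Sequence[bool], y: Sequence[bool]) -> float:
    """d = 1 − 2|x∧y| / (|x|+|y|); undefined (error) when both vectors are empty."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    tot = int(x.sum()) + int(y.sum())
    if tot == 0:
        raise ValueError("Dice dissimilarity undefined for two empty vectors")
    return 1.0 - 2.0 * int((x & y).sum()) / tot


def cluster_dtuples(
    m: CellByTupleMatrix, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of d-tuple columns under Dice dissimilarity."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    k = m.n_tuples
    if k < 2:
        return Dendrogram(linkage=np.zeros((0, 4)), n_leaves=k)
    dists = pdist(m.values.T.astype(bool), metric="dice")
    z = sch.linkage(dists, method=linkage)
    # guard against tiny negative heights from floating error
    z[:, 2] = np.maximum(z[:, 2], 0.0)
    return Dendrogram(linkage=z, n_leaves=k)


def modularity(similarity: np.ndarray, labels: np.ndarray) -> float:
    """Newman weighted modularity of a labelling on a similarity graph.

    Q = (1/2W)·Σ_{ij, same cluster} (w_ij − k_i·k_j / 2W) with zero
    diagonal; a graph of zero total weight has Q = 0 for every partition.
    """
    w = np.asarray(similarity, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    two_w = w.sum()  # = 2W, both triangles
    if two_w <= 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() - k[idx].sum() ** 2 / two_w
    return q / two_w


def modularity_cut(
    dend: Dendrogram,
    m: CellByTupleMatrix,
    override_height: Optional[float] = None,
) -> tuple[np.ndarray, float, float]:
    """Pick the merge height maximising modularity (or use an override).

    Returns (labels, Q, height). Candidate heights are 0 plus every
    distinct merge height (the partition is piecewise constant between
    merges); ties are broken towards the smallest height, i.e. the finest
    partition.
    """
    sim = 1.0 - squareform(pdist(m.values.T.astype(bool), metric="dice")) if (
        m.n_tuples >= 2
    ) else np.zeros((m.n_tuples, m.n_tuples))
    if override_height is not None:
        labels = dend.cut(override_height)
        return labels, modularity(sim, labels), float(override_height)
    heights = np.concatenate([[0.0], np.unique(dend.merge_heights)])
    best: Optional[tuple[np.ndarray, float, float]] = None
    for h in heights:
        labels = dend.cut(h)
        q = modularity(sim, labels)
        if best is None or q > best[1] + 1e-12:
            best = (labels, q, float(h))
    assert best is not None
    return best


@dataclass
class StateDefinition:
    state_id: int
    dtuples: list[DTuple]
    cells: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    cut_height: float = np.nan

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


def assign_states(
    partition: np.ndarray, m: CellByTupleMatrix, cut_height: float = np.nan
) -> list[StateDefinition]:
    """One state per cluster; a cell joins a state iff it carries ≥1 of its d-tuples."""
    partition = np.asarray(partition)
    if partition.shape != (m.n_tuples,):
        raise ValueError("partition must label every d-tuple")
    states = []
    for sid, c in enumerate(np.unique(partition)):
        idx = np.nonzero(partition == c)[0]
        cells = m.values[:, idx].any(axis=1)
        states.append(
            StateDefinition(
                state_id=sid,
                dtuples=[m.tuple_index[i] for i in idx],
                cells=cells,
                cut_height=cut_height,
            )
        )
    return states


def project_states(
    states: Sequence[StateDefinition], b2: BinaryMatrix
) -> dict[str, set[int]]:
    """Map each cell of a new dataset to the states whose d-tuples it carries.

    Membership is by exact joint-state match of each d-tuple's genes (all
    other genes ignored); no re-estimation happens. Genes missing from the
    new matrix raise an error listing them.
    """
    missing = sorted(
        {g for st in states for dt in st.dtuples for g in dt.genes}
        - set(b2.gene_names)
    )
    if missing:
        raise KeyError(f"genes absent from the projection target: {missing}")
    out: dict[str, set[int]] = {c: set() for c in b2.cell_ids}
    for st in states:
        members = np.zeros(b2.n_cells, dtype=bool)
        for dt in st.dtuples:
            members |= member_cell_mask(b2, dt.genes, dt.state)
        for i in np.nonzero(members)[0]:
            out[b2.cell_ids[i]].add(st.state_id)
    return out


def state_table(states: Sequence[StateDefinition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "state_id": st.state_id,
                "n_dtuples": len(st.dtuples),
                "n_cells": st.n_cells,
                "cut_height": st.cut_height,
            }
            for st in states
        ],
        columns=["state_id", "n_dtuples", "n_cells", "cut_height"],
    )


def cell_state_matrix(
    states: Sequence[StateDefinition], cell_ids: Sequence[str]
) -> pd.DataFrame:
    """Cells x states boolean table plus implicit per-cell counts."""
    data = {f"state_{st.state_id}": st.cells.astype(int) for st in states}
    return pd.DataFrame(data, index=list(cell_ids))
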