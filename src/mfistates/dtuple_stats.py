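"""Deviating gene tuples (d-tuples) under the exact binomial null.

Under independence, the number of conditioned cells Φ_s observing joint
state s of an n-gene tuple is Binomial(N, π_s) with
π_s = Π_i (s_i·μ_i + (1−s_i)(1−μ_i)), where μ_i is gene i's mean on the
conditioned cells. Positively deviating states (log2 fold change over
π_s·N greater than zero) get an exact upper-tail p-value; one global
Benjamini–Yekutieli family across all retained interactions controls the
FDR under dependence. Cells carrying a d-tuple are counted on the full
matrix, ignoring the blanket state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .data_io import BinaryMatrix
from .mfi_estimation import InteractionEstimate, condition_cells

NEG_INF = float("-inf")


@dataclass
class DTuple:
    genes: tuple[str, ...]
    state: tuple[int, ...]
    phi: int
    N: int
    pi: float
    log2fc: float
    p: float
    q: float = np.nan
    member_cells: Optional[np.ndarray] = None  # boolean over the full matrix

    @property
    def n_member_cells(self) -> int:
        return 0 if self.member_cells is None else int(self.member_cells.sum())

    @property
    def state_label(self) -> str:
        return " ".join(
            f"{g}{'+' if s else '-'}" for g, s in zip(self.genes, self.state)
        )

    @property
    def key(self) -> tuple:
        return (self.genes, self.state)


def null_prob(mu: Sequence[float], s: Sequence[int]) -> float:
    """π_s = Π_i (s_i·μ_i + (1−s_i)(1−μ_i)) — independent-gene state probability."""
    mu = np.asarray(mu, dtype=float)
    s = np.asarray(s, dtype=float)
    if mu.shape != s.shape:
        raise ValueError("mu and s must have equal length")
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("each mu must lie in [0, 1]")
    return float(np.prod(s * mu + (1 - s) * (1 - mu)))


def dtuple_pvalue(phi: int, N: int, pi: float) -> float:
    """Exact upper-tail binomial p = P(Φ ≥ phi) via the survival function."""
    if not 0 <= phi <= N:
        raise ValueError("phi must satisfy 0 <= phi <= N")
    if phi == 0:
        return 1.0
    return float(binom.sf(phi - 1, N, pi))


def dtuple_log2fc(phi: int, N: int, pi: float) -> float:
    """log2(phi / (pi·N)); −inf for phi = 0; undefined (error) for pi = 0."""
    if N <= 0:
        raise ValueError("N must be positive")
    if pi <= 0:
        raise ValueError("log2 fold change undefined for pi = 0")
    if phi == 0:
        return NEG_INF
    return float(np.log2(phi / (pi * N)))


def adjust_by(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up q-values (dependence-robust FDR)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_by")[1]


@dataclass
class DTupleConfig:
    fdr: float = 0.05
    min_log2fc: float = 3.0  # eightfold enrichment over expected
    min_cells: int = 0


def extract_dtuples(
    interactions: Sequence[InteractionEstimate],
    b: BinaryMatrix,
    config: DTupleConfig = DTupleConfig(),
) -> list[DTuple]:
    """Significant positively deviating joint states of retained interactions.

    Every 2ⁿ joint state of every retained interaction is evaluated on the
    interaction's own conditioned cells (μ and φ both counted there);
    positive deviations form one global BY family; survivors must pass
    q < fdr, log2fc > min_log2fc and carry at least min_cells cells on the
    full matrix. States with π_s = 0 (degenerate μ) are skipped.
    """
    candidates: list[DTuple] = []
    seen: set[tuple] = set()
    for est in interactions:
        if not est.retained:
            continue
        mask = condition_cells(b, est.spec)
        N = int(mask.sum())
        if N == 0:
            continue
        cols = [b.gene_index(g) for g in est.genes]
        sub = b.values[np.ix_(mask.nonzero()[0], cols)]
        mu = sub.mean(axis=0)
        n = len(est.genes)
        codes = sub @ (2 ** np.arange(n - 1, -1, -1))
        counts = np.bincount(codes, minlength=2**n)
        for idx, s in enumerate(itertools.product((0, 1), repeat=n)):
            pi = null_prob(mu, s)
            if pi <= 0:
                continue
            phi = int(counts[idx])
            fc = dtuple_log2fc(phi, N, pi)
            if fc <= 0:
                continue
            dt = DTuple(
                genes=est.genes,
                state=s,
                phi=phi,
                N=N,
                pi=pi,
                log2fc=fc,
                p=dtuple_pvalue(phi, N, pi),
            )
            if dt.key in seen:
                continue
            seen.add(dt.key)
            candidates.append(dt)
    if not candidates:
        return []
    qvals = adjust_by([dt.p for dt in candidates])
    out: list[DTuple] = []
    for dt, q in zip(candidates, qvals):
        dt.q = float(q)
        if dt.q >= config.fdr or dt.log2fc <= config.min_log2fc:
            continue
        dt.member_cells = member_cell_mask(b, dt.genes, dt.state)
        if dt.n_member_cells < config.min_cells:
            continue
        out.append(dt)
    return out


def member_cell_mask(
    b: BinaryMatrix, genes: Sequence[str], state: Sequence[int]
) -> np.ndarray:
    """Cells matching the tuple's joint state on the full matrix (blanket ignored)."""
    mask = np.ones(b.n_cells, dtype=bool)
    for g, s in zip(genes, state):
        mask &= b.values[:, b.gene_index(g)] == s
    return mask


def dtuple_table(dtuples: Sequence[DTuple]) -> pd.DataFrame:
    """Summary-table rows: genes, state, φ, N, π, log2FC, p, q, member count."""
    rows = [
        {
            "genes": ",".join(dt.genes),
            "state": dt.state_label,
            "phi": dt.phi,
            "N": dt.N,
            "pi": dt.pi,
            "log2fc": dt.log2fc,
            "p": dt.p,
            "q": dt.q,
            "n_member_cells": dt.n_member_cells,
        }
        for dt in dtuples
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genes",
            "state",
            "phi",
            "N",
            "pi",
            "log2fc",
            "p",
            "q",
            "n_member_cells",
        ],
    )
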