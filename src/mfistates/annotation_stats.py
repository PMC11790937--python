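"""Scoring inferred states against external annotations.

Enrichment / depletion of an annotation label inside a state is tested
with the exact hypergeometric tail (over-representation:
P(X ≥ q) with N cells total, m in the state, k in the annotation, q in
both), optionally a two-sided Fisher exact test; p-values are corrected
with Benjamini–Hochberg across all state x label pairs and reported as
−log10(q) for heatmaps. Differential expression between a state and the
rest (s2o) or between two states after dropping co-labelled cells (s2s)
uses a Wilcoxon rank-sum test on log-normalised expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix


@dataclass
class EnrichmentResult:
    N: int
    m: int
    k: int
    q_overlap: int
    mode: str
    p: float
    q_adj: float = np.nan
    odds_ratio: Optional[float] = None

    @property
    def neg_log10_q(self) -> float:
        return float(-np.log10(max(self.q_adj, np.finfo(float).tiny)))


def enrichment_test(
    N: int, m: int, k: int, q_overlap: int, mode: str = "enrich"
) -> EnrichmentResult:
    """Exact test of state/annotation overlap.

    enrich: p = P(X ≥ q) (hypergeometric upper tail, as computed by
    phyper(q−1, m, N−m, k, lower.tail=FALSE)); deplete: p = P(X ≤ q);
    fisher_two_sided: exact two-sided p on the table
    [[q, m−q], [k−q, N−m−k+q]] with the sample odds ratio.
    """
    if not (0 <= q_overlap <= min(m, k) and m <= N and k <= N and m + k - q_overlap <= N):
        raise ValueError(
            f"inconsistent counts N={N}, m={m}, k={k}, q={q_overlap}"
        )
    dist = hypergeom(M=N, n=m, N=k)
    odds = None
    if mode == "enrich":
        p = float(dist.sf(q_overlap - 1))
    elif mode == "deplete":
        p = float(dist.cdf(q_overlap))
    elif mode == "fisher_two_sided":
        table = [[q_overlap, m - q_overlap], [k - q_overlap, N - m - k + q_overlap]]
        odds, p = fisher_exact(table, alternative="two-sided")
        odds = float(odds)
        p = float(p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EnrichmentResult(
        N=N, m=m, k=k, q_overlap=q_overlap, mode=mode, p=min(p, 1.0), odds_ratio=odds
    )


def adjust_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def enrichment_matrix(
    state_cells: Mapping[str, np.ndarray],
    annotations: Mapping[str, np.ndarray],
    mode: str = "enrich",
) -> pd.DataFrame:
    """State x label table of −log10(BH-adjusted p); masks index the same cells."""
    results: list[EnrichmentResult] = []
    keys: list[tuple[str, str]] = []
    n_total: Optional[int] = None
    for sname, smask in state_cells.items():
        smask = np.asarray(smask, dtype=bool)
        if n_total is None:
            n_total = smask.size
        for aname, amask in annotations.items():
            amask = np.asarray(amask, dtype=bool)
            res = enrichment_test(
                N=n_total,
                m=int(smask.sum()),
                k=int(amask.sum()),
                q_overlap=int((smask & amask).sum()),
                mode=mode,
            )
            results.append(res)
            keys.append((sname, aname))
    qvals = adjust_bh([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q_adj = float(q)
    df = pd.DataFrame(
        {
            "state": [s for s, _ in keys],
            "label": [a for _, a in keys],
            "value": [r.neg_log10_q for r in results],
        }
    )
    return df.pivot(index="state", columns="label", values="value")


@dataclass
class DifferentialExpressionRecord:
    gene: str
    log2fc: float
    p: float
    q_adj: float
    direction: str  # "up" means higher in group a


@dataclass
class DEConfig:
    max_q: float = 0.05
    min_abs_log2fc: float = 0.25
    min_cells: int = 3
    pseudocount: float = 1e-9
    scale: float = 1e4


def differential_expression(
    expr: ExpressionMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    mode: str = "s2s",
    config: DEConfig = DEConfig(),
) -> list[DifferentialExpressionRecord]:
    """Wilcoxon rank-sum DE between two cell groups on log-normalised values.

    s2s: the two masks are two states' cells and the intersection is
    removed from both before testing; s2o: cells_b should be the
    complement of the state. Counts are scaled to `scale` per cell; the
    test runs on log1p of that and the fold change compares group means on
    the normalised (exp) scale with pseudocount ε. BH adjustment spans all
    testable genes; records are filtered at q < max_q, |log2fc| > min_abs_log2fc.
    """
    a = np.asarray(cells_a, dtype=bool).copy()
    bmask = np.asarray(cells_b, dtype=bool).copy()
    if mode == "s2s":
        both = a & bmask
        a &= ~both
        bmask &= ~both
    elif mode != "s2o":
        raise ValueError(f"unknown mode {mode!r}")
    if a.sum() < config.min_cells or bmask.sum() < config.min_cells:
        raise ValueError(
            f"each group needs at least {config.min_cells} cells "
            f"(got {int(a.sum())} and {int(bmask.sum())})"
        )
    totals = expr.values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, expr.values / totals * config.scale, 0.0)
    logn = np.log1p(norm)
    eps = config.pseudocount
    genes, pvals, fcs = [], [], []
    for j, gene in enumerate(expr.gene_names):
        xa, xb = logn[a, j], logn[bmask, j]
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            continue  # constant gene: untestable
        _, p = mannwhitneyu(xa, xb, alternative="two-sided")
        fc = float(np.log2((norm[a, j].mean() + eps) / (norm[bmask, j].mean() + eps)))
        genes.append(gene)
        pvals.append(float(p))
        fcs.append(fc)
    qvals = adjust_bh(pvals)
    out = []
    for gene, p, q, fc in zip(genes, pvals, qvals, fcs):
        if q < config.max_q and abs(fc) > config.min_abs_log2fc:
            out.append(
                DifferentialExpressionRecord(
                    gene=gene,
                    log2fc=fc,
                    p=p,
                    q_adj=float(q),
                    direction="up" if fc > 0 else "down",
                )
            )
    return out


def match_markers(
    degs: Sequence[DifferentialExpressionRecord],
    marker_sets: Mapping[str, Sequence[str]],
    m_min: int = 3,
) -> list[dict]:
    """Candidate labels whose markers intersect the upregulated DEGs.

    A label qualifies when ≥ m_min of its markers are upregulated; results
    are ranked by hit count, then hit fraction of the DEG list.
    """
    up = [d.gene for d in degs if d.direction == "up"]
    up_set = set(up)
    out = []
    for label, markers in marker_sets.items():
        hits = [g for g in markers if g in up_set]
        if len(hits) >= m_min:
            out.append(
                {
                    "label": label,
                    "n_hits": len(hits),
                    "hit_fraction": len(hits) / len(up) if up else 0.0,
                    "genes": hits,
                }
            )
    out.sort(key=lambda r: (-r["n_hits"], -r["hit_fraction"], r["label"]))
    return out


def read_annotation_tsv(path: str, cell_ids: Sequence[str]) -> dict[str, np.ndarray]:
    """Two-column (cell_id, label) TSV → per-label boolean masks over cell_ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"])
    index = {c: i for i, c in enumerate(cell_ids)}
    out: dict[str, np.ndarray] = {}
    for label, grp in df.groupby("label"):
        mask = np.zeros(len(cell_ids), dtype=bool)
        for c in grp["cell_id"]:
            if c in index:
                mask[index[c]] = True
        out[str(label)] = mask
    return out
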