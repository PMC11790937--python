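"""Model-free interaction (MFI) estimation with bootstrap sign-stability.

The n-point MFI of a gene tuple (G₁..Gₙ), conditioned on its Markov
blanket being in a fixed state (all-zero by default), is the alternating
log-linear contrast

    I = Σ_{s ∈ {0,1}ⁿ}  (−1)^{n−|s|} · ln p(G = s | blanket in state),

the generalised conditional log-odds ratio. For n = 2 this is
ln(p₁₁p₀₀ / p₁₀p₀₁); for n = 3 the eight-term odds-ratio-of-odds-ratios.
The natural-log scale makes the MFI equal the coupling J of a {0,1}
energy model p(x) ∝ exp(Σ_T J_T Π_{i∈T} x_i) when one generated the data.

Uncertainty is quantified by bootstrap: the full cell set is resampled
with replacement and re-conditioned in every resample. Because the
estimate depends on the data only through the 2ⁿ joint-state counts of
conditioned cells (everything else enters as a single "unconditioned"
lump), the resampled counts follow a multinomial over those 2ⁿ+1
categories; sampling that multinomial directly is distributionally
identical to resampling cells and far cheaper. An interaction is retained
when the fraction λ of defined bootstrap estimates whose sign differs
from the point estimate is below a threshold (default 0.05).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .data_io import BinaryMatrix
from .dependency_graph import DependencyGraph, markov_blanket, per_gene_blankets

MAX_ORDER = 7


@dataclass(frozen=True)
class ConditionSpec:
    """Blanket genes pinned to 0 and (optionally) to 1 during estimation."""

    zero_genes: frozenset = frozenset()
    one_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "zero_genes", frozenset(self.zero_genes))
        object.__setattr__(self, "one_genes", frozenset(self.one_genes))
        if self.zero_genes & self.one_genes:
            raise ValueError("zero_genes and one_genes must be disjoint")

    @property
    def genes(self) -> frozenset:
        return self.zero_genes | self.one_genes

    @classmethod
    def from_blanket(
        cls, blanket: Iterable[str], genes_to_one: Iterable[str] = ()
    ) -> "ConditionSpec":
        blanket = frozenset(blanket)
        ones = blanket & frozenset(genes_to_one)
        return cls(zero_genes=blanket - ones, one_genes=ones)


@dataclass
class InteractionEstimate:
    genes: tuple[str, ...]
    value: Optional[float]
    defined: bool
    n_conditioned_cells: int
    spec: ConditionSpec = field(default_factory=ConditionSpec)
    bootstrap_values: Optional[np.ndarray] = None
    lam: Optional[float] = None
    unstable: bool = False
    retained: bool = False
    state_counts: Optional[np.ndarray] = None  # 2ⁿ joint-state counts

    @property
    def order(self) -> int:
        return len(self.genes)

    @property
    def value_log2(self) -> Optional[float]:
        return None if self.value is None else self.value / np.log(2.0)


def condition_cells(b: BinaryMatrix, spec: ConditionSpec) -> np.ndarray:
    """Boolean mask of cells whose blanket genes sit in the required state."""
    mask = np.ones(b.n_cells, dtype=bool)
    for g in spec.zero_genes:
        mask &= b.values[:, b.gene_index(g)] == 0
    for g in spec.one_genes:
        mask &= b.values[:, b.gene_index(g)] == 1
    return mask


def _state_counts(
    b: BinaryMatrix, genes: Sequence[str], mask: np.ndarray
) -> np.ndarray:
    """Counts of the 2ⁿ joint states among masked cells, index = binary code."""
    code = np.zeros(b.n_cells, dtype=np.int64)
    for g in genes:
        code = code * 2 + b.values[:, b.gene_index(g)]
    return np.bincount(code[mask], minlength=2 ** len(genes)).astype(np.int64)


def _signs(n: int) -> np.ndarray:
    """(−1)^(n−|s|) for each joint state s in binary-code order."""
    states = np.array(list(itertools.product((0, 1), repeat=n)))
    return np.where((n - states.sum(axis=1)) % 2 == 0, 1.0, -1.0)


def _mfi_from_counts(counts: np.ndarray, signs: np.ndarray) -> Optional[float]:
    if np.any(counts == 0):
        return None
    # the Σ signs · ln N term cancels (signs sum to zero), so raw counts suffice
    return float(np.dot(signs, np.log(counts)))


def estimate_mfi(
    b: BinaryMatrix, genes: Sequence[str], spec: ConditionSpec = ConditionSpec()
) -> InteractionEstimate:
    """Plug-in MFI point estimate on the conditioned cells (natural log)."""
    genes = tuple(genes)
    n = len(genes)
    if not 2 <= n <= MAX_ORDER:
        raise ValueError(f"tuple order must be 2..{MAX_ORDER}, got {n}")
    if set(genes) & spec.genes:
        raise ValueError("tuple genes must be disjoint from conditioning genes")
    mask = condition_cells(b, spec)
    counts = _state_counts(b, genes, mask)
    value = _mfi_from_counts(counts, _signs(n))
    return InteractionEstimate(
        genes=genes,
        value=value,
        defined=value is not None,
        n_conditioned_cells=int(mask.sum()),
        spec=spec,
        state_counts=counts,
    )


def bootstrap_mfi(
    b: BinaryMatrix,
    genes: Sequence[str],
    spec: ConditionSpec = ConditionSpec(),
    n_boot: int = 1000,
    seed: int = 0,
    min_defined: int = 100,
) -> InteractionEstimate:
    """Point estimate plus bootstrap distribution and sign-flip fraction λ.

    λ counts only defined resamples (those observing every joint state) in
    its denominator; fewer than `min_defined` defined resamples flags the
    estimate unstable. Deterministic given `seed`.
    """
    est = estimate_mfi(b, genes, spec)
    if not est.defined:
        raise ValueError(f"point estimate for {est.genes} is undefined")
    rng = np.random.default_rng(seed)
    n = len(est.genes)
    counts = est.state_counts
    # categories: the 2ⁿ conditioned joint states + all unconditioned cells
    cats = np.concatenate([counts, [b.n_cells - counts.sum()]])
    probs = cats / b.n_cells
    resampled = rng.multinomial(b.n_cells, probs, size=n_boot)[:, : 2 ** n]
    defined = np.all(resampled > 0, axis=1)
    signs = _signs(n)
    with np.errstate(divide="ignore"):
        boot = np.log(resampled[defined].astype(float)) @ signs
    n_def = int(defined.sum())
    lam = (
        float(np.mean(np.sign(boot) != np.sign(est.value))) if n_def else np.nan
    )
    est.bootstrap_values = boot
    est.lam = lam
    est.unstable = n_def < min_defined
    return est


# ---------------------------------------------------------------------------
# candidate enumeration


def mutual_mb_graph(g: DependencyGraph) -> dict[str, set[str]]:
    """Adjacency i-j iff i ∈ MB(j) and j ∈ MB(i)."""
    blankets = per_gene_blankets(g)
    adj: dict[str, set[str]] = {x: set() for x in g.nodes}
    for i, j in itertools.combinations(g.nodes, 2):
        if i in blankets[j] and j in blankets[i]:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def enumerate_candidates(
    g: DependencyGraph,
    orders: Sequence[int] = (2, 3, 4, 5),
    prior_hits: Optional[Mapping[int, Sequence[tuple[str, ...]]]] = None,
) -> dict[int, list[tuple[str, ...]]]:
    """Candidate gene tuples per interaction order.

    Order 2: every unordered pair. Orders 3-5: cliques of that size in the
    mutual-Markov-blanket graph (Markov-disconnected tuples have vanishing
    interactions). Orders 6-7: each significant 5-/6-tuple from
    `prior_hits` extended by one gene of the tuple's blanket.
    """
    prior_hits = prior_hits or {}
    out: dict[int, list[tuple[str, ...]]] = {}
    adj = mutual_mb_graph(g)
    for order in sorted(orders):
        if not 2 <= order <= MAX_ORDER:
            raise ValueError(f"order {order} outside 2..{MAX_ORDER}")
        if order == 2:
            out[2] = list(itertools.combinations(g.nodes, 2))
        elif order <= 5:
            out[order] = _cliques_of_size(adj, order)
        else:
            if order - 1 not in prior_hits:
                raise ValueError(
                    f"order-{order} candidates need significant "
                    f"{order - 1}-tuples in prior_hits"
                )
            seen: set[tuple[str, ...]] = set()
            cands: list[tuple[str, ...]] = []
            for tup in prior_hits[order - 1]:
                mb = markov_blanket(g, tup).blanket
                for extra in sorted(mb):
                    new = tuple(sorted(set(tup) | {extra}))
                    if len(new) == order and new not in seen:
                        seen.add(new)
                        cands.append(new)
            out[order] = cands
    return out


def _cliques_of_size(adj: Mapping[str, set[str]], k: int) -> list[tuple[str, ...]]:
    """All k-cliques, enumerated by ordered extension (no duplicates)."""
    nodes = sorted(adj)
    cliques = [(x,) for x in nodes]
    for _ in range(k - 1):
        nxt = []
        for c in cliques:
            last = c[-1]
            for x in sorted(adj[last]):
                if x > last and all(x in adj[y] for y in c):
                    nxt.append(c + (x,))
        cliques = nxt
    return cliques


# ---------------------------------------------------------------------------
# full scan


@dataclass
class ScanConfig:
    orders: tuple[int, ...] = (2, 3, 4, 5)
    extend_orders: tuple[int, ...] = ()  # add 6 and/or 7 to chain from hits
    n_boot: int = 1000
    lambda_threshold: float = 0.05
    min_defined: int = 100
    genes_to_one: tuple[str, ...] = ()
    max_candidates_per_order: Optional[int] = None
    seed: int = 0


def choose_condition_spec(
    b: BinaryMatrix,
    g: DependencyGraph,
    genes: Sequence[str],
    genes_to_one: Iterable[str] = (),
) -> ConditionSpec:
    """Best-powered admissible conditioning set for a tuple.

    The MFI may be estimated conditioning on the tuple's union blanket or,
    through the factorised form, on any single member's blanket; among
    those admissible sets the one retaining the most cells is chosen
    (ties: fewer genes, then lexicographic) — the smallest usable blanket
    in the statistical-power sense.
    """
    genes = tuple(genes)
    union_mb = markov_blanket(g, genes).blanket
    candidates = {union_mb}
    for x in genes:
        candidates.add(markov_blanket(g, (x,)).blanket - set(genes))
    best: Optional[tuple[int, int, tuple, ConditionSpec]] = None
    for mb in candidates:
        spec = ConditionSpec.from_blanket(mb, genes_to_one)
        n_cells = int(condition_cells(b, spec).sum())
        key = (-n_cells, len(mb), tuple(sorted(mb)))
        if best is None or key < best[:3]:
            best = (*key, spec)
    assert best is not None
    return best[3]


def run_interaction_scan(
    b: BinaryMatrix, g: DependencyGraph, config: ScanConfig = ScanConfig()
) -> list[InteractionEstimate]:
    """Estimate every candidate tuple; mark those passing the λ filter.

    Returns all attempted estimates (including inestimable ones) with
    `retained` flagged; orders 6/7 (if requested) chain from the retained
    5-/6-tuples. Deterministic given `config.seed`.
    """
    results: list[InteractionEstimate] = []
    hits: dict[int, list[tuple[str, ...]]] = {}
    seed_root = np.random.SeedSequence(config.seed)

    def scan_order(order: int, cands: list[tuple[str, ...]]) -> None:
        if config.max_candidates_per_order is not None and len(cands) > (
            config.max_candidates_per_order
        ):
            cands = cands[: config.max_candidates_per_order]
        child_seeds = seed_root.spawn(len(cands) + 1)[1:] if cands else []
        for tup, ss in zip(cands, child_seeds):
            spec = choose_condition_spec(b, g, tup, config.genes_to_one)
            est = estimate_mfi(b, tup, spec)
            if est.defined and est.n_conditioned_cells > 0:
                est = bootstrap_mfi(
                    b,
                    tup,
                    spec,
                    n_boot=config.n_boot,
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                    min_defined=config.min_defined,
                )
                est.retained = (
                    not est.unstable and est.lam < config.lambda_threshold
                )
            if est.retained:
                hits.setdefault(len(tup), []).append(tup)
            results.append(est)

    base = enumerate_candidates(g, orders=config.orders)
    for order in sorted(base):
        scan_order(order, base[order])
    for order in sorted(config.extend_orders):
        prior = {order - 1: hits.get(order - 1, [])}
        if not prior[order - 1]:
            continue
        ext = enumerate_candidates(g, orders=(order,), prior_hits=prior)
        scan_order(order, ext[order])
    return results


def scan_table(results: Sequence[InteractionEstimate]):
    """One row per candidate, matching the TSV output contract."""
    import pandas as pd

    rows = []
    for est in results:
        rows.append(
            {
                "genes": ",".join(est.genes),
                "order": est.order,
                "value": est.value if est.defined else np.nan,
                "lambda": est.lam if est.lam is not None else np.nan,
                "n_conditioned_cells": est.n_conditioned_cells,
                "defined": est.defined,
                "retained": est.retained,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genes",
            "order",
            "value",
            "lambda",
            "n_conditioned_cells",
            "defined",
            "retained",
        ],
    )
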