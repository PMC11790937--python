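"""Synthetic binary expression with known ground truth.

Three families of generators cover every pipeline stage:

* {0,1} energy models p(x) ∝ exp(Σ_T J_T Π_{i∈T} x_i) with arbitrary
  singleton fields and higher-order couplings, sampled by exact
  enumeration (≤ 20 genes) — the population MFI of a planted coupling T,
  conditioned on all other genes being 0, equals J_T exactly, which makes
  `exact_mfi_from_model` the oracle for the estimator;
* binary Bayesian networks with explicit CPTs, ancestrally sampled — the
  fixture for structure learning;
* independent-Bernoulli global nulls and frequency-targeted d-tuple
  planting/removal on existing matrices.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_io import BinaryMatrix
from .dtuple_stats import member_cell_mask

MAX_ENUM_GENES = 20


def _gene_names(n: int) -> list[str]:
    return [f"g{i}" for i in range(n)]


@dataclass
class EnergyModel:
    """Energy model over n binary genes: couplings map tuples of gene indices to J."""

    n_genes: int
    couplings: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes > MAX_ENUM_GENES:
            raise ValueError(
                f"exact enumeration capped at {MAX_ENUM_GENES} genes "
                f"(got {self.n_genes}); larger models are refused"
            )
        norm: dict[tuple[int, ...], float] = {}
        for tup, j in self.couplings.items():
            tup = tuple(sorted(int(i) for i in tup))
            if len(set(tup)) != len(tup):
                raise ValueError(f"coupling {tup} repeats a gene")
            if any(i < 0 or i >= self.n_genes for i in tup):
                raise ValueError(f"coupling {tup} outside 0..{self.n_genes - 1}")
            norm[tup] = norm.get(tup, 0.0) + float(j)
        self.couplings = norm

    def state_log_weights(self) -> np.ndarray:
        """Unnormalised log-probability of each of the 2ⁿ states (binary-code order)."""
        states = np.array(
            list(itertools.product((0, 1), repeat=self.n_genes)), dtype=float
        )
        logw = np.zeros(len(states))
        for tup, j in self.couplings.items():
            logw += j * states[:, list(tup)].prod(axis=1)
        return logw

    def probabilities(self) -> np.ndarray:
        logw = self.state_log_weights()
        logw -= logw.max()  # overflow guard
        w = np.exp(logw)
        return w / w.sum()

    @classmethod
    def from_json(cls, path: str) -> "EnergyModel":
        with open(path) as fh:
            spec = json.load(fh)
        return cls(
            n_genes=int(spec["n_genes"]),
            couplings={
                tuple(entry["genes"]): float(entry["J"])
                for entry in spec.get("couplings", [])
            },
        )


def sample_energy_model(
    model: EnergyModel, n_cells: int, seed: int = 0
) -> BinaryMatrix:
    """Multinomial draw of cells from the exactly enumerated distribution."""
    rng = np.random.default_rng(seed)
    probs = model.probabilities()
    counts = rng.multinomial(n_cells, probs)
    states = np.array(
        list(itertools.product((0, 1), repeat=model.n_genes)), dtype=np.int8
    )
    values = np.repeat(states, counts, axis=0)
    rng.shuffle(values, axis=0)
    return BinaryMatrix(
        values=values,
        gene_names=_gene_names(model.n_genes),
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
    )


def exact_mfi_from_model(model: EnergyModel, genes: Sequence[int]) -> float:
    """Population MFI of a gene tuple, all non-tuple genes conditioned to 0.

    Computed from the enumerated probabilities; equals J_tuple to machine
    precision whenever the model's couplings involving the tuple's genes
    reduce to that single term under the all-zero conditioning.
    """
    genes = tuple(sorted(int(i) for i in genes))
    if any(i < 0 or i >= model.n_genes for i in genes):
        raise ValueError(f"tuple {genes} outside the model's genes")
    n = len(genes)
    probs = model.probabilities()
    states = np.array(list(itertools.product((0, 1), repeat=model.n_genes)))
    others = [i for i in range(model.n_genes) if i not in genes]
    cond = (
        np.all(states[:, others] == 0, axis=1)
        if others
        else np.ones(len(states), dtype=bool)
    )
    total = 0.0
    for s in itertools.product((0, 1), repeat=n):
        sel = cond & np.all(states[:, list(genes)] == np.array(s), axis=1)
        p = probs[sel].sum()
        sign = 1.0 if (n - sum(s)) % 2 == 0 else -1.0
        total += sign * np.log(p)
    return float(total)


# ---------------------------------------------------------------------------
# Bayesian networks


@dataclass
class BinaryBayesNet:
    """Fully directed binary Bayesian network with explicit CPTs.

    `cpts[node]` maps each joint parent state (tuple of 0/1, parents in
    sorted order) to P(node = 1 | parents).
    """

    nodes: list[str]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, dict[tuple[int, ...], float]]

    def __post_init__(self) -> None:
        order = self.topological_order()  # raises on cycles
        for node in self.nodes:
            ps = self.parents.get(node, ())
            for state in itertools.product((0, 1), repeat=len(ps)):
                p = self.cpts[node][state]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"CPT entry {node}{state} = {p} outside [0,1]")
        self._order = order

    def topological_order(self) -> list[str]:
        seen: dict[str, int] = {}
        out: list[str] = []

        def visit(x: str) -> None:
            if seen.get(x) == 1:
                raise ValueError("the DAG contains a cycle")
            if seen.get(x) == 2:
                return
            seen[x] = 1
            for p in self.parents.get(x, ()):
                visit(p)
            seen[x] = 2
            out.append(x)

        for x in self.nodes:
            visit(x)
        return out


def sample_bayes_net(
    net: BinaryBayesNet, n_cells: int, seed: int = 0
) -> BinaryMatrix:
    """Ancestral sampling in topological order; deterministic given seed."""
    rng = np.random.default_rng(seed)
    idx = {x: i for i, x in enumerate(net.nodes)}
    values = np.zeros((n_cells, len(net.nodes)), dtype=np.int8)
    for node in net._order:
        ps = net.parents.get(node, ())
        if ps:
            codes = [tuple(row) for row in values[:, [idx[p] for p in ps]]]
            p1 = np.array([net.cpts[node][c] for c in codes])
        else:
            p1 = np.full(n_cells, net.cpts[node][()])
        values[:, idx[node]] = rng.random(n_cells) < p1
    return BinaryMatrix(
        values=values,
        gene_names=list(net.nodes),
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
    )


# ---------------------------------------------------------------------------
# global nulls and d-tuple planting


def null_independent(
    n_cells: int, mus: Sequence[float], seed: int = 0
) -> BinaryMatrix:
    """Independent Bernoulli columns with the given means."""
    mus = np.asarray(mus, dtype=float)
    if np.any(mus < 0) or np.any(mus > 1):
        raise ValueError("each mean must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = (rng.random((n_cells, mus.size)) < mus).astype(np.int8)
    return BinaryMatrix(
        values=values,
        gene_names=_gene_names(mus.size),
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
    )


def plant_dtuple(
    b: BinaryMatrix,
    genes: Sequence[str],
    state: Sequence[int],
    fold: float,
    seed: int = 0,
    cells: Optional[np.ndarray] = None,
) -> BinaryMatrix:
    """Force a joint state's frequency to fold x its independence expectation.

    The targeted genes' sub-vectors of the eligible cells are resampled
    from the mixture  t·δ_state + (1−t)·Q, where t = fold·π_state (π from
    the current gene means on the eligible cells) and Q is the product of
    adjusted marginals m_i = (μ_i − t·s_i)/(1−t) restricted to states
    other than the target. This hits the target frequency exactly in
    expectation while approximately preserving each gene's marginal mean;
    fold < 1 depletes the state (fold = 0 removes it entirely). Only the
    targeted genes' columns change; `cells` optionally restricts planting
    to a boolean cell subset. Deterministic given seed.
    """
    genes = tuple(genes)
    state = tuple(int(s) for s in state)
    if fold < 0:
        raise ValueError("fold must be non-negative")
    if len(genes) != len(state):
        raise ValueError("genes and state must have equal length")
    cols = [b.gene_index(g) for g in genes]
    eligible = (
        np.ones(b.n_cells, dtype=bool) if cells is None else np.asarray(cells, bool)
    )
    sub = b.values[np.ix_(eligible.nonzero()[0], cols)]
    mu = sub.mean(axis=0)
    pi = float(np.prod([m if s else 1 - m for m, s in zip(mu, state)]))
    t = fold * pi
    if t > 1:
        raise ValueError(
            f"infeasible fold: target frequency {t:.4f} exceeds 1"
        )
    s_arr = np.array(state, dtype=float)
    if t < 1:
        m_adj = (mu - t * s_arr) / (1 - t)
    else:
        m_adj = s_arr
    if np.any(m_adj < -1e-12) or np.any(m_adj > 1 + 1e-12):
        raise ValueError(
            "infeasible fold: adjusted marginals leave [0,1]; "
            "lower the fold or the target state's probability"
        )
    m_adj = np.clip(m_adj, 0.0, 1.0)
    # product distribution over the 2ⁿ sub-states with the target removed
    n = len(genes)
    states = np.array(list(itertools.product((0, 1), repeat=n)), dtype=float)
    pq = np.prod(
        states * m_adj + (1 - states) * (1 - m_adj), axis=1
    )
    target_idx = int("".join(map(str, state)), 2)
    pq[target_idx] = 0.0
    if pq.sum() <= 0:
        pq = np.ones(2**n)
        pq[target_idx] = 0.0
    pq = pq / pq.sum()
    mix = (1 - t) * pq
    mix[target_idx] = t
    rng = np.random.default_rng(seed)
    n_elig = int(eligible.sum())
    draws = rng.choice(2**n, size=n_elig, p=mix)
    new_sub = states[draws].astype(np.int8)
    values = b.values.copy()
    values[np.ix_(eligible.nonzero()[0], cols)] = new_sub
    return BinaryMatrix(
        values=values, gene_names=list(b.gene_names), cell_ids=list(b.cell_ids)
    )


def plant_disjoint_pair(
    b: BinaryMatrix,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    state: Sequence[int],
    fold: float,
    seed: int = 0,
) -> BinaryMatrix:
    """Plant the same state on two gene tuples with exactly disjoint member cells.

    Tuple A is planted first; tuple B's state is then removed (fold 0)
    from A's member cells and planted only outside them, at the
    within-subset frequency that restores the global fold target. The two
    resulting d-tuples label exactly disjoint cell sets.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31, size=3)
    planted = plant_dtuple(b, genes_a, state, fold, seed=int(seeds[0]))
    members_a = member_cell_mask(planted, genes_a, state)
    planted = plant_dtuple(
        planted, genes_b, state, fold=0.0, seed=int(seeds[1]), cells=members_a
    )
    outside = ~members_a
    frac_outside = outside.mean()
    mu_b = planted.values[:, [planted.gene_index(g) for g in genes_b]].mean(axis=0)
    pi_global = float(
        np.prod([m if s else 1 - m for m, s in zip(mu_b, state)])
    )
    mu_out = planted.values[np.ix_(outside.nonzero()[0],
                                   [planted.gene_index(g) for g in genes_b])].mean(axis=0)
    pi_out = float(np.prod([m if s else 1 - m for m, s in zip(mu_out, state)]))
    # within-subset fold chosen so the global frequency hits fold·π(global)
    fold_within = fold * pi_global / (pi_out * frac_outside)
    return plant_dtuple(
        planted, genes_b, state, fold=fold_within, seed=int(seeds[2]), cells=outside
    )


def write_metadata(path: str, generator: str, seed: int, **params) -> None:
    """Sidecar JSON recording how a matrix was generated."""
    with open(path, "w") as fh:
        json.dump({"generator": generator, "seed": seed, **params}, fh, indent=2)
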