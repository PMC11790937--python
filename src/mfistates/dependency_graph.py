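"""Conditional-dependency structure learning and Markov blankets.

The graph over genes is learnt in two stages, mirroring common hybrid
structure-learning practice on binary data:

1. a stable (order-independent) PC skeleton search with likelihood-ratio
   G² conditional-independence tests, majority-rule v-structure
   orientation and Meek propagation, yielding a CPDAG;
2. a score-based refinement: BDeu hill-climbing over DAGs initialised
   from a consistent extension of the CPDAG, with restarts, allowed to
   add edges the PC stage missed.

The graph is never interpreted causally here; its only downstream use is
to provide Markov blankets (parents + children + spouses) that make the
interaction estimates better-powered. Blankets are computed conservatively
on the CPDAG: an undirected edge is treated as both orientations, so the
blanket is a superset of the blanket in any DAG of the equivalence class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .data_io import BinaryMatrix


# ---------------------------------------------------------------------------
# graph container


class DependencyGraph:
    """Partially directed graph (CPDAG) over gene names."""

    def __init__(self, nodes: Sequence[str]):
        self.nodes: list[str] = list(nodes)
        self._nodeset = set(self.nodes)
        if len(self._nodeset) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._undirected: set[frozenset] = set()
        self._directed: set[tuple[str, str]] = set()
        self.sepsets: dict[frozenset, list[frozenset]] = {}

    # -- edits ---------------------------------------------------------
    def _check(self, *genes: str) -> None:
        for g in genes:
            if g not in self._nodeset:
                raise KeyError(f"unknown gene {g!r}")

    def add_undirected(self, a: str, b: str) -> None:
        self._check(a, b)
        if a == b:
            raise ValueError("self-edges are not allowed")
        self._directed.discard((a, b))
        self._directed.discard((b, a))
        self._undirected.add(frozenset((a, b)))

    def add_directed(self, a: str, b: str) -> None:
        self._check(a, b)
        if a == b:
            raise ValueError("self-edges are not allowed")
        self._undirected.discard(frozenset((a, b)))
        self._directed.discard((b, a))
        self._directed.add((a, b))

    def remove_edge(self, a: str, b: str) -> None:
        self._undirected.discard(frozenset((a, b)))
        self._directed.discard((a, b))
        self._directed.discard((b, a))

    # -- queries -------------------------------------------------------
    def is_adjacent(self, a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in self._undirected
            or (a, b) in self._directed
            or (b, a) in self._directed
        )

    def adjacent(self, a: str) -> set[str]:
        out = {b for e in self._undirected if a in e for b in e if b != a}
        out |= {y for (x, y) in self._directed if x == a}
        out |= {x for (x, y) in self._directed if y == a}
        return out

    def parents(self, a: str) -> set[str]:
        return {x for (x, y) in self._directed if y == a}

    def children(self, a: str) -> set[str]:
        return {y for (x, y) in self._directed if x == a}

    def undirected_neighbors(self, a: str) -> set[str]:
        return {b for e in self._undirected if a in e for b in e if b != a}

    def edges(self) -> list[tuple[str, str, str]]:
        """(gene_a, gene_b, orientation) rows; orientation in {directed, undirected}."""
        rows = [(a, b, "directed") for (a, b) in sorted(self._directed)]
        rows += [
            (a, b, "undirected") for a, b in sorted(tuple(sorted(e)) for e in self._undirected)
        ]
        return rows

    def n_edges(self) -> int:
        return len(self._undirected) + len(self._directed)

    def has_directed_path(self, src: str, dst: str) -> bool:
        stack, seen = [src], set()
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            if x in seen:
                continue
            seen.add(x)
            stack.extend(self.children(x))
        return False

    def copy(self) -> "DependencyGraph":
        g = DependencyGraph(self.nodes)
        g._undirected = set(self._undirected)
        g._directed = set(self._directed)
        g.sepsets = {k: list(v) for k, v in self.sepsets.items()}
        return g

    # -- io --------------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\torientation\n")
            for a, b, o in self.edges():
                fh.write(f"{a}\t{b}\t{o}\n")

    @classmethod
    def from_tsv(cls, path: str, nodes: Sequence[str]) -> "DependencyGraph":
        g = cls(nodes)
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "gene_a\tgene_b\torientation":
                raise ValueError(f"{path}: unexpected edge-list header {header!r}")
            for line in fh:
                a, b, o = line.rstrip("\n").split("\t")
                if o == "directed":
                    g.add_directed(a, b)
                elif o == "undirected":
                    g.add_undirected(a, b)
                else:
                    raise ValueError(f"{path}: unknown orientation {o!r}")
        return g


@dataclass
class MarkovBlanket:
    targets: tuple[str, ...]
    blanket: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        self.blanket = frozenset(self.blanket) - set(self.targets)


# ---------------------------------------------------------------------------
# conditional-independence test


def ci_test(
    b: BinaryMatrix, i: str, j: str, cond: Iterable[str] = ()
) -> tuple[float, float]:
    """Likelihood-ratio G² test of i ⫫ j | cond on binary data.

    The 2x2 table of (i, j) is formed within every observed joint state
    (stratum) of the conditioning genes; G² = 2·Σ O·ln(O/E) summed over
    strata, with each stratum contributing (rows₊−1)(cols₊−1) degrees of
    freedom (so strata with a zero margin contribute nothing). Degenerate
    tables return (0.0, 1.0).
    """
    cond = [g for g in cond]
    if i == j or i in cond or j in cond:
        raise ValueError("i, j and cond must be distinct")
    xi = b.values[:, b.gene_index(i)].astype(np.int64)
    xj = b.values[:, b.gene_index(j)].astype(np.int64)
    if cond:
        code = np.zeros(b.n_cells, dtype=np.int64)
        for g in cond:
            code = code * 2 + b.values[:, b.gene_index(g)]
        n_strata = 2 ** len(cond)
    else:
        code = np.zeros(b.n_cells, dtype=np.int64)
        n_strata = 1
    cell = code * 4 + xi * 2 + xj
    counts = np.bincount(cell, minlength=n_strata * 4).reshape(n_strata, 2, 2)
    g2 = 0.0
    df = 0
    for tab in counts:
        rows = tab.sum(axis=1)
        cols = tab.sum(axis=0)
        n = tab.sum()
        r_pos = int((rows > 0).sum())
        c_pos = int((cols > 0).sum())
        d = (r_pos - 1) * (c_pos - 1)
        if d == 0 or n == 0:
            continue
        expected = np.outer(rows, cols) / n
        mask = tab > 0
        g2 += 2.0 * float((tab[mask] * np.log(tab[mask] / expected[mask])).sum())
        df += d
    if df == 0:
        return 0.0, 1.0
    return g2, float(chi2.sf(g2, df))


# ---------------------------------------------------------------------------
# PC skeleton + orientation


def _subsets(items: Sequence[str], size: int) -> Iterable[tuple[str, ...]]:
    return itertools.combinations(sorted(items), size)


def pc_skeleton(
    b: BinaryMatrix, alpha: float = 0.05, max_cond: int = 3
) -> DependencyGraph:
    """Stable PC search returning a CPDAG.

    Edges are removed level-by-level in conditioning-set size; removals
    within a level are applied only after the level completes, so the
    result does not depend on gene order. v-structures are oriented with
    the majority rule over all qualifying separating sets, and Meek rules
    propagate the orientations.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    g = DependencyGraph(b.gene_names)
    nodes = g.nodes
    for a, c in itertools.combinations(nodes, 2):
        g.add_undirected(a, c)

    for level in range(max_cond + 1):
        adj_snapshot = {x: g.adjacent(x) for x in nodes}
        removals: list[tuple[str, str]] = []
        any_testable = False
        for a, c in itertools.combinations(nodes, 2):
            if not g.is_adjacent(a, c):
                continue
            candidate_sets: list[tuple[str, ...]] = []
            for base in (adj_snapshot[a] - {c}, adj_snapshot[c] - {a}):
                if len(base) >= level:
                    candidate_sets.extend(_subsets(base, level))
            seen: set[tuple[str, ...]] = set()
            separated = False
            for S in candidate_sets:
                if S in seen:
                    continue
                seen.add(S)
                any_testable = True
                _, p = ci_test(b, a, c, S)
                if p > alpha:
                    g.sepsets.setdefault(frozenset((a, c)), []).append(frozenset(S))
                    separated = True
                    break
            if separated:
                removals.append((a, c))
        for a, c in removals:
            g.remove_edge(a, c)
        if not any_testable:
            break

    _orient_majority_colliders(g, b, alpha, max_cond)
    apply_meek_rules(g)
    return g


def _orient_majority_colliders(
    g: DependencyGraph, b: BinaryMatrix, alpha: float, max_cond: int
) -> None:
    """Orient unshielded triples a - k - c as colliders by the majority rule.

    For each triple all separating sets (subsets of the final adjacencies
    of a and of c, up to max_cond) are re-evaluated; k's absence from more
    than half of them orients a→k←c. Exactly half leaves the triple
    unoriented (ambiguous); an orientation that would reverse an existing
    directed edge is skipped.
    """
    orientations: list[tuple[str, str]] = []
    for k in g.nodes:
        nbrs = sorted(g.adjacent(k))
        for a, c in itertools.combinations(nbrs, 2):
            if g.is_adjacent(a, c):
                continue
            sepsets: list[frozenset] = []
            seen: set[tuple[str, ...]] = set()
            for base in (g.adjacent(a) - {c}, g.adjacent(c) - {a}):
                for size in range(min(len(base), max_cond) + 1):
                    for S in _subsets(base, size):
                        if S in seen:
                            continue
                        seen.add(S)
                        _, p = ci_test(b, a, c, S)
                        if p > alpha:
                            sepsets.append(frozenset(S))
            if not sepsets:
                sepsets = g.sepsets.get(frozenset((a, c)), [])
            if not sepsets:
                continue
            frac_with_k = sum(1 for S in sepsets if k in S) / len(sepsets)
            if frac_with_k < 0.5:
                orientations.extend([(a, k), (c, k)])
    for x, y in orientations:
        if (y, x) in g._directed:  # conflicting collider claims: leave alone
            continue
        if frozenset((x, y)) in g._undirected or (x, y) in g._directed:
            g.add_directed(x, y)


def apply_meek_rules(g: DependencyGraph) -> None:
    """Propagate orientations with Meek rules R1-R3 until fixpoint.

    R4 is only required when orientations come from background knowledge,
    which never happens here. An orientation that would create a directed
    cycle is skipped.
    """

    def orient(x: str, y: str) -> bool:
        if frozenset((x, y)) not in g._undirected:
            return False
        if g.has_directed_path(y, x):
            return False
        g.add_directed(x, y)
        return True

    changed = True
    while changed:
        changed = False
        undirected = [tuple(sorted(e)) for e in sorted(g._undirected, key=sorted)]
        for a, b_ in undirected:
            for x, y in ((a, b_), (b_, a)):
                # R1: z→x, x—y, z and y nonadjacent => x→y
                if any(
                    not g.is_adjacent(z, y) for z in g.parents(x) if z != y
                ):
                    if orient(x, y):
                        changed = True
                        break
                # R2: x→z→y and x—y => x→y
                if any(z in g.parents(y) for z in g.children(x)):
                    if orient(x, y):
                        changed = True
                        break
                # R3: x—z1, x—z2, z1→y, z2→y, z1 and z2 nonadjacent => x→y
                z_parents = [
                    z
                    for z in g.undirected_neighbors(x)
                    if z != y and y in g.children(z)
                ]
                if any(
                    not g.is_adjacent(z1, z2)
                    for z1, z2 in itertools.combinations(sorted(z_parents), 2)
                ):
                    if orient(x, y):
                        changed = True
                        break
            if changed:
                break


# ---------------------------------------------------------------------------
# BDeu hill-climbing refinement


def bdeu_family_score(
    b: BinaryMatrix, child: int, parents: tuple[int, ...], ess: float = 1.0
) -> float:
    """BDeu local score of one node given an (index-based) parent set."""
    x = b.values[:, child].astype(np.int64)
    q = 2 ** len(parents)
    if parents:
        code = np.zeros(b.n_cells, dtype=np.int64)
        for p in parents:
            code = code * 2 + b.values[:, p]
    else:
        code = np.zeros(b.n_cells, dtype=np.int64)
    counts = np.bincount(code * 2 + x, minlength=q * 2).reshape(q, 2)
    nj = counts.sum(axis=1)
    aj = ess / q
    ajk = ess / (2 * q)
    score = float(
        np.sum(gammaln(aj) - gammaln(aj + nj))
        + np.sum(gammaln(ajk + counts) - gammaln(ajk))
    )
    return score


class _DagState:
    """Mutable DAG over node indices with cached BDeu family scores."""

    def __init__(self, b: BinaryMatrix, ess: float):
        self.b = b
        self.ess = ess
        self.n = b.n_genes
        self.parents: list[set[int]] = [set() for _ in range(self.n)]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_score(self, child: int, parents: Iterable[int]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = bdeu_family_score(self.b, child, key[1], self.ess)
        return self._cache[key]

    def score(self) -> float:
        return sum(self.family_score(i, self.parents[i]) for i in range(self.n))

    def has_path(self, src: int, dst: int) -> bool:
        """Directed path src→...→dst; adding dst→src would then close a cycle."""
        stack, seen = [src], set()
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            if x in seen:
                continue
            seen.add(x)
            stack.extend(c for c in range(self.n) if x in self.parents[c])
        return False

    def creates_cycle(self, src: int, dst: int) -> bool:
        """Would adding src→dst close a directed cycle?"""
        return self.has_path(dst, src)


def _dag_to_cpdag(nodes: Sequence[str], parents: list[set[int]]) -> DependencyGraph:
    """Equivalence-class pattern: skeleton + v-structures + Meek closure."""
    g = DependencyGraph(nodes)
    for child, ps in enumerate(parents):
        for p in ps:
            g.add_undirected(nodes[p], nodes[child])
    for child, ps in enumerate(parents):
        for p1, p2 in itertools.combinations(sorted(ps), 2):
            # unshielded collider: the two parents are themselves nonadjacent
            if not g.is_adjacent(nodes[p1], nodes[p2]):
                g.add_directed(nodes[p1], nodes[child])
                g.add_directed(nodes[p2], nodes[child])
    apply_meek_rules(g)
    return g


def consistent_extension(g: DependencyGraph) -> list[set[int]]:
    """Orient a CPDAG into a DAG without new v-structures (Dor & Tarsi).

    Falls back to orienting remaining undirected edges along a topological
    order when the pattern is not perfectly extendable (possible for
    finite-sample PC output).
    """
    work = g.copy()
    nodes = g.nodes
    idx = {x: i for i, x in enumerate(nodes)}
    parents: list[set[int]] = [set() for _ in nodes]
    for (a, b_) in g._directed:
        parents[idx[b_]].add(idx[a])
    remaining = set(nodes)
    progress = True
    while remaining and progress:
        progress = False
        for x in sorted(remaining):
            if work.children(x) & remaining:
                continue
            und = work.undirected_neighbors(x) & remaining
            adj_x = work.adjacent(x) & remaining
            if all(
                work.is_adjacent(y, z)
                for y in und
                for z in adj_x
                if y != z
            ):
                for y in und:
                    parents[idx[x]].add(idx[y])
                    work.add_directed(y, x)
                remaining.discard(x)
                progress = True
                break
    # fallback for non-extendable patterns
    leftover = [tuple(sorted(e)) for e in work._undirected]
    for a, b_ in sorted(leftover):
        if not work.has_directed_path(b_, a):
            work.add_directed(a, b_)
            parents[idx[b_]].add(idx[a])
        else:
            work.add_directed(b_, a)
            parents[idx[a]].add(idx[b_])
    return parents


def refine_score(
    g: DependencyGraph,
    b: BinaryMatrix,
    restarts: int = 2,
    seed: int = 0,
    ess: float = 1.0,
) -> DependencyGraph:
    """Greedy BDeu hill-climbing refinement of a CPDAG.

    Starts from a consistent extension of `g`; add/delete/reverse moves are
    scanned in a fixed lexicographic order and the first improving move is
    taken (deterministic given `seed`). Later restarts perturb the start
    DAG with seeded random legal edge additions/removals, and the best DAG
    found across restarts is returned as its CPDAG. The search may add
    edges absent from `g`.
    """
    rng = np.random.default_rng(seed)
    base_parents = consistent_extension(g)
    best_parents: Optional[list[set[int]]] = None
    best_score = -np.inf
    for r in range(max(1, restarts)):
        state = _DagState(b, ess)
        state.parents = [set(p) for p in base_parents]
        if r > 0:
            _perturb(state, rng, n_moves=state.n)
        _hill_climb(state)
        s = state.score()
        if s > best_score + 1e-12:
            best_score = s
            best_parents = [set(p) for p in state.parents]
    assert best_parents is not None
    return _dag_to_cpdag(b.gene_names, best_parents)


def _perturb(state: _DagState, rng: np.random.Generator, n_moves: int) -> None:
    n = state.n
    for _ in range(n_moves):
        x, y = rng.integers(0, n, size=2)
        if x == y:
            continue
        if x in state.parents[y]:
            state.parents[y].discard(x)
        elif y not in state.parents[x] and not state.creates_cycle(int(x), int(y)):
            state.parents[y].add(int(x))


def _hill_climb(state: _DagState, tol: float = 1e-9) -> None:
    n = state.n
    improved = True
    while improved:
        improved = False
        for x in range(n):
            for y in range(n):
                if x == y:
                    continue
                old_y = state.family_score(y, state.parents[y])
                if x in state.parents[y]:
                    # delete x→y
                    delta = state.family_score(y, state.parents[y] - {x}) - old_y
                    if delta > tol:
                        state.parents[y].discard(x)
                        improved = True
                        continue
                    # reverse x→y to y→x
                    if not _reverse_creates_cycle(state, x, y):
                        old_x = state.family_score(x, state.parents[x])
                        delta = (
                            state.family_score(y, state.parents[y] - {x})
                            + state.family_score(x, state.parents[x] | {y})
                            - old_y
                            - old_x
                        )
                        if delta > tol:
                            state.parents[y].discard(x)
                            state.parents[x].add(y)
                            improved = True
                elif y not in state.parents[x]:
                    # add x→y
                    if state.creates_cycle(x, y):
                        continue
                    delta = state.family_score(y, state.parents[y] | {x}) - old_y
                    if delta > tol:
                        state.parents[y].add(x)
                        improved = True


def _reverse_creates_cycle(state: _DagState, x: int, y: int) -> bool:
    # after removing x→y, does a path x→...→y remain? then y→x closes a cycle
    state.parents[y].discard(x)
    try:
        return state.creates_cycle(y, x)
    finally:
        state.parents[y].add(x)


# ---------------------------------------------------------------------------
# Markov blankets


def markov_blanket(g: DependencyGraph, targets: Sequence[str]) -> MarkovBlanket:
    """Parents ∪ children ∪ spouses of each target, conservatively on a CPDAG.

    Undirected edges are treated as both orientations, so the returned
    blanket is a superset of the Markov blanket in every DAG of the
    equivalence class. For a tuple of targets the per-gene blankets are
    unioned and the targets themselves removed.
    """
    targets = tuple(targets)
    for t in targets:
        if t not in g._nodeset:
            raise KeyError(f"unknown target gene {t!r}")
    blanket: set[str] = set()
    for t in targets:
        blanket |= g.adjacent(t)  # parents, children, undirected neighbours
        possible_children = g.children(t) | g.undirected_neighbors(t)
        for c in possible_children:
            blanket |= g.parents(c) | g.undirected_neighbors(c)
    return MarkovBlanket(targets=targets, blanket=frozenset(blanket) - set(targets))


def per_gene_blankets(g: DependencyGraph) -> dict[str, frozenset]:
    return {x: markov_blanket(g, (x,)).blanket for x in g.nodes}
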