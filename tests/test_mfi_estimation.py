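import itertools

import numpy as np
import pytest

from mfistates.data_io import BinaryMatrix
from mfistates.dependency_graph import DependencyGraph
from mfistates.mfi_estimation import (
    ConditionSpec,
    ScanConfig,
    bootstrap_mfi,
    condition_cells,
    enumerate_candidates,
    estimate_mfi,
    run_interaction_scan,
)
from mfistates.synthetic_data import (
    EnergyModel,
    exact_mfi_from_model,
    null_independent,
    sample_energy_model,
)


def from_counts(counts: dict, genes) -> BinaryMatrix:
    """Build a matrix whose joint-state counts are exactly `counts`."""
    rows = []
    for state, n in counts.items():
        rows.extend([list(state)] * n)
    return BinaryMatrix(
        values=np.array(rows),
        gene_names=list(genes),
        cell_ids=[f"c{i}" for i in range(len(rows))],
    )


class TestConditionCells:
    def test_empty_spec_keeps_all(self, make_binary):
        b = make_binary([[0, 1], [1, 0]])
        assert condition_cells(b, ConditionSpec()).sum() == 2

    def test_zero_gene_on_all_ones(self, make_binary):
        b = make_binary([[1], [1]], genes=["g"])
        assert condition_cells(b, ConditionSpec(zero_genes={"g"})).sum() == 0

    def test_selects_matching_cells(self, make_binary):
        b = make_binary([[0], [0], [1], [0]], genes=["g"])
        mask = condition_cells(b, ConditionSpec(zero_genes={"g"}))
        np.testing.assert_array_equal(mask, [True, True, False, True])

    def test_one_genes(self, make_binary):
        b = make_binary([[0, 1], [1, 1], [1, 0]], genes=["a", "b"])
        mask = condition_cells(
            b, ConditionSpec(zero_genes={"a"}, one_genes={"b"})
        )
        np.testing.assert_array_equal(mask, [True, False, False])


class TestEstimateMFI:
    def test_two_point_log_odds_ratio(self):
        b = from_counts(
            {(1, 1): 40, (0, 0): 40, (1, 0): 10, (0, 1): 10}, ["a", "b"]
        )
        est = estimate_mfi(b, ("a", "b"))
        assert est.value == pytest.approx(np.log(16), rel=1e-12)

    def test_equiprobable_states_give_zero(self):
        b = from_counts({s: 25 for s in itertools.product((0, 1), repeat=2)}, "ab")
        assert estimate_mfi(b, ("a", "b")).value == pytest.approx(0.0, abs=1e-12)

    def test_unobserved_state_undefined(self):
        counts = {s: 5 for s in itertools.product((0, 1), repeat=3)}
        counts[(1, 1, 1)] = 0
        b = from_counts(counts, "abc")
        est = estimate_mfi(b, ("a", "b", "c"))
        assert not est.defined and est.value is None

    def test_symmetric_under_gene_permutation(self):
        rng = np.random.default_rng(3)
        counts = {
            s: int(rng.integers(5, 50))
            for s in itertools.product((0, 1), repeat=3)
        }
        b = from_counts(counts, "abc")
        vals = {
            estimate_mfi(b, perm).value
            for perm in itertools.permutations(("a", "b", "c"))
        }
        assert max(vals) - min(vals) < 1e-10

    def test_general_formula_reduces_to_pairwise_odds_ratio(self):
        rng = np.random.default_rng(4)
        counts = {
            s: int(rng.integers(5, 60))
            for s in itertools.product((0, 1), repeat=2)
        }
        b = from_counts(counts, "ab")
        n = {s: counts[s] for s in counts}
        expected = np.log(
            (n[(1, 1)] * n[(0, 0)]) / (n[(1, 0)] * n[(0, 1)])
        )
        assert estimate_mfi(b, ("a", "b")).value == pytest.approx(expected)

    def test_general_formula_reduces_to_three_point_ratio(self):
        rng = np.random.default_rng(5)
        counts = {
            s: int(rng.integers(5, 60))
            for s in itertools.product((0, 1), repeat=3)
        }
        b = from_counts(counts, "abc")
        N = sum(counts.values())
        p = {s: c / N for s, c in counts.items()}
        expected = np.log(
            (p[1, 1, 1] * p[1, 0, 0] * p[0, 1, 0] * p[0, 0, 1])
            / (p[1, 1, 0] * p[1, 0, 1] * p[0, 1, 1] * p[0, 0, 0])
        )
        assert estimate_mfi(b, ("a", "b", "c")).value == pytest.approx(expected)

    def test_conditioning_excluded_from_tuple(self):
        b = from_counts({(0, 0): 10, (1, 1): 10}, "ab")
        with pytest.raises(ValueError):
            estimate_mfi(b, ("a", "b"), ConditionSpec(zero_genes={"a"}))


class TestBootstrap:
    def test_strong_interaction_lambda_near_zero(self):
        model = EnergyModel(2, {(0, 1): np.log(16)})
        b = sample_energy_model(model, 10000, seed=1)
        est = bootstrap_mfi(b, ("g0", "g1"), seed=2)
        assert est.lam < 0.01

    def test_null_lambda_near_half(self):
        b = null_independent(10000, [0.5, 0.5], seed=3)
        est = bootstrap_mfi(b, ("g0", "g1"), seed=4)
        assert 0.3 < est.lam < 0.7

    def test_deterministic_given_seed(self):
        b = null_independent(2000, [0.4, 0.4], seed=5)
        e1 = bootstrap_mfi(b, ("g0", "g1"), seed=42)
        e2 = bootstrap_mfi(b, ("g0", "g1"), seed=42)
        np.testing.assert_array_equal(e1.bootstrap_values, e2.bootstrap_values)

    def test_null_bootstrap_interval_covers_zero(self):
        covered = 0
        for seed in range(30):
            b = null_independent(5000, [0.5, 0.5], seed=100 + seed)
            est = bootstrap_mfi(b, ("g0", "g1"), seed=seed)
            lo, hi = np.percentile(est.bootstrap_values, [2.5, 97.5])
            covered += lo <= 0.0 <= hi
        assert covered >= 26  # ~95% coverage with Monte-Carlo slack


def graph_with_mutual_triangle():
    g = DependencyGraph(["A", "B", "C", "D"])
    g.add_undirected("A", "B")
    g.add_undirected("B", "C")
    g.add_undirected("A", "C")
    return g


class TestEnumerateCandidates:
    def test_empty_graph_pairs_only(self):
        g = DependencyGraph(list("wxyz"))
        cands = enumerate_candidates(g, orders=(2, 3))
        assert len(cands[2]) == 6
        assert cands[3] == []

    def test_triangle_gives_triple(self):
        cands = enumerate_candidates(graph_with_mutual_triangle(), orders=(3,))
        assert cands[3] == [("A", "B", "C")]

    def test_extension_by_blanket(self):
        g = DependencyGraph(list("abcdefg"))
        for pair in itertools.combinations("abcde", 2):
            g.add_undirected(*pair)
        g.add_undirected("e", "f")
        g.add_undirected("e", "g")
        tup = ("a", "b", "c", "d", "e")
        cands = enumerate_candidates(g, orders=(6,), prior_hits={5: [tup]})
        assert set(cands[6]) == {
            tuple(sorted(set(tup) | {"f"})),
            tuple(sorted(set(tup) | {"g"})),
        }

    def test_six_needs_prior_hits(self):
        g = DependencyGraph(list("ab"))
        with pytest.raises(ValueError):
            enumerate_candidates(g, orders=(6,))


class TestInteractionScan:
    def test_global_null_retains_few(self):
        b = null_independent(8000, np.linspace(0.2, 0.5, 6), seed=9)
        g = DependencyGraph(b.gene_names)  # empty graph: pairs only
        res = run_interaction_scan(b, g, ScanConfig(n_boot=500, seed=1))
        retained = [e for e in res if e.retained]
        assert len(res) == 15
        assert len(retained) <= 5  # λ filter keeps the null mostly empty

    def test_planted_triple_recovered_with_value(self):
        J = 1.5
        model = EnergyModel(3, {(0, 1, 2): J})
        b = sample_energy_model(model, 50000, seed=10)
        g = graph_with_mutual_triangle()
        g2 = DependencyGraph(b.gene_names)
        g2.add_undirected("g0", "g1")
        g2.add_undirected("g1", "g2")
        g2.add_undirected("g0", "g2")
        res = run_interaction_scan(b, g2, ScanConfig(seed=2))
        triple = next(e for e in res if e.genes == ("g0", "g1", "g2"))
        assert triple.retained
        assert triple.value == pytest.approx(J, abs=0.15)

    def test_zero_conditioned_cells_not_retained(self, make_binary):
        b = make_binary([[1, 0, 1], [1, 1, 0], [1, 0, 0]], genes=["z", "a", "b"])
        g = DependencyGraph(b.gene_names)
        g.add_directed("z", "a")
        g.add_directed("z", "b")
        g.add_undirected("a", "b")
        res = run_interaction_scan(b, g, ScanConfig(orders=(2,), seed=0))
        pair = next(e for e in res if set(e.genes) == {"a", "b"})
        assert not pair.retained
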