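import itertools

import numpy as np
import pytest

from mfistates.dtuple_stats import DTuple
from mfistates.state_inference import (
    CellByTupleMatrix,
    assign_states,
    cluster_dtuples,
    dice_dissimilarity,
    modularity,
    modularity_cut,
    project_states,
)


def ctm_from_columns(cols) -> CellByTupleMatrix:
    values = np.array(cols, dtype=bool).T
    dts = [
        DTuple(
            genes=(f"g{j}",),
            state=(1,),
            phi=int(values[:, j].sum()),
            N=values.shape[0],
            pi=0.5,
            log2fc=1.0,
            p=0.01,
            member_cells=values[:, j],
        )
        for j in range(values.shape[1])
    ]
    return CellByTupleMatrix(
        values=values,
        tuple_index=dts,
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
    )


class TestDice:
    def test_identical_vectors(self):
        x = [True, False, True]
        assert dice_dissimilarity(x, x) == pytest.approx(0.0)

    def test_disjoint_supports(self):
        assert dice_dissimilarity([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_half_overlap(self):
        x = [1, 1, 0, 0]
        y = [0, 1, 1, 0]
        assert dice_dissimilarity(x, y) == pytest.approx(0.5)

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            dice_dissimilarity([0, 0], [0, 0])

    def test_violates_triangle_inequality(self):
        # a known witness: d(x,z) > d(x,y) + d(y,z)
        x = [1, 1, 0]
        y = [1, 1, 1]
        z = [0, 1, 1]
        assert dice_dissimilarity(x, z) > (
            dice_dissimilarity(x, y) + dice_dissimilarity(y, z)
        )


class TestClusterDtuples:
    def test_identical_columns_merge_at_zero(self):
        col = [1, 1, 0, 0, 1]
        dend = cluster_dtuples(ctm_from_columns([col, col]))
        assert dend.merge_heights[0] == pytest.approx(0.0)

    def test_two_identical_plus_disjoint(self):
        a = [1, 1, 0, 0]
        c = [0, 0, 1, 1]
        dend = cluster_dtuples(ctm_from_columns([a, a, c]))
        np.testing.assert_allclose(dend.merge_heights, [0.0, 1.0])

    def test_column_permutation_leaves_partitions_unchanged(self):
        rng = np.random.default_rng(1)
        cols = [rng.random(30) < 0.4 for _ in range(6)]
        ctm = ctm_from_columns(cols)
        dend = cluster_dtuples(ctm)
        labels, _, _ = modularity_cut(dend, ctm)
        perm = [3, 1, 5, 0, 2, 4]
        ctm2 = ctm_from_columns([cols[i] for i in perm])
        dend2 = cluster_dtuples(ctm2)
        labels2, _, _ = modularity_cut(dend2, ctm2)
        # same partition up to relabelling
        part1 = {tuple(sorted(np.nonzero(labels == c)[0])) for c in set(labels)}
        inv = np.argsort(perm)
        part2 = {
            tuple(sorted(int(inv[i]) for i in np.nonzero(labels2 == c)[0]))
            for c in set(labels2)
        }
        # map indices of ctm2 columns back to original positions
        part2 = {
            tuple(sorted(perm[i] for i in grp))
            for grp in (
                tuple(np.nonzero(labels2 == c)[0]) for c in set(labels2)
            )
        }
        assert part1 == part2

    def test_single_tuple_trivial(self):
        dend = cluster_dtuples(ctm_from_columns([[1, 0]]))
        assert dend.n_leaves == 1
        assert dend.linkage.shape[0] == 0

    def test_newick_export(self):
        a = [1, 1, 0, 0]
        c = [0, 0, 1, 1]
        nwk = cluster_dtuples(ctm_from_columns([a, a, c])).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2


class TestModularityCut:
    def test_two_disjoint_groups_recovered_with_q_half(self):
        a = [1, 1, 0, 0]
        c = [0, 0, 1, 1]
        ctm = ctm_from_columns([a, a, c, c])
        dend = cluster_dtuples(ctm)
        labels, q, h = modularity_cut(dend, ctm)
        assert len(set(labels)) == 2
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert q == pytest.approx(0.5)

    def test_single_cluster_partition_q_zero(self):
        rng = np.random.default_rng(2)
        cols = [rng.random(20) < 0.5 for _ in range(5)]
        ctm = ctm_from_columns(cols)
        from scipy.spatial.distance import pdist, squareform

        sim = 1 - squareform(pdist(ctm.values.T, metric="dice"))
        assert modularity(sim, np.zeros(5, dtype=int)) == pytest.approx(0.0)

    def test_override_zero_gives_singletons(self):
        rng = np.random.default_rng(3)
        cols = [rng.random(40) < 0.5 for _ in range(4)]
        ctm = ctm_from_columns(cols)
        dend = cluster_dtuples(ctm)
        labels, _, h = modularity_cut(dend, ctm, override_height=0.0)
        assert len(set(labels)) == 4 and h == 0.0

    def test_cut_partitions_are_nested(self):
        rng = np.random.default_rng(4)
        cols = [rng.random(30) < 0.4 for _ in range(7)]
        ctm = ctm_from_columns(cols)
        dend = cluster_dtuples(ctm)
        heights = sorted(set(dend.merge_heights))
        for h_low, h_high in zip(heights, heights[1:]):
            fine = dend.cut(h_low)
            coarse = dend.cut(h_high)
            # every fine cluster maps into exactly one coarse cluster
            for c in set(fine):
                assert len(set(coarse[fine == c])) == 1

    def test_matches_exhaustive_partition_search(self):
        # two clean groups: the hierarchical optimum equals the global one
        a = [1, 1, 0, 0, 0]
        b = [1, 1, 1, 0, 0]
        c = [0, 0, 0, 1, 1]
        d = [0, 0, 1, 1, 1]
        ctm = ctm_from_columns([a, b, c, d])
        from scipy.spatial.distance import pdist, squareform

        sim = 1 - squareform(pdist(ctm.values.T, metric="dice"))
        best_q = max(
            modularity(sim, np.array(labels))
            for labels in itertools.product(range(4), repeat=4)
        )
        dend = cluster_dtuples(ctm)
        _, q, _ = modularity_cut(dend, ctm)
        assert q == pytest.approx(best_q, abs=1e-12)


class TestAssignAndProject:
    def test_multi_label_cell(self):
        a = [1, 0, 1]
        c = [0, 1, 1]
        ctm = ctm_from_columns([a, c])
        states = assign_states(np.array([0, 1]), ctm)
        # cell 2 carries both d-tuples
        assert states[0].cells[2] and states[1].cells[2]
        assert not states[0].cells[1] and not states[1].cells[0]

    def test_cell_without_dtuple_has_no_state(self):
        ctm = ctm_from_columns([[1, 0], [0, 0]])
        states = assign_states(np.array([0, 1]), ctm)
        assert not any(st.cells[1] for st in states)

    def test_singleton_cluster_cells(self):
        col = [1, 0, 1, 0]
        ctm = ctm_from_columns([col])
        states = assign_states(np.array([0]), ctm)
        np.testing.assert_array_equal(states[0].cells, np.array(col, dtype=bool))

    def test_projection_idempotent_on_training_matrix(self, make_binary):
        b = make_binary(
            np.random.default_rng(5).integers(0, 2, (50, 4)), genes=list("wxyz")
        )
        dts = [
            DTuple(genes=("w", "x"), state=(1, 1), phi=1, N=50, pi=0.2,
                   log2fc=1.0, p=0.01),
            DTuple(genes=("y", "z"), state=(1, 0), phi=1, N=50, pi=0.2,
                   log2fc=1.0, p=0.01),
        ]
        ctm = CellByTupleMatrix.from_dtuples(dts, b)
        states = assign_states(np.array([0, 1]), ctm)
        proj = project_states(states, b)
        for i, cell in enumerate(b.cell_ids):
            expected = {st.state_id for st in states if st.cells[i]}
            assert proj[cell] == expected

    def test_projection_requires_exact_state_match(self, make_binary):
        b2 = make_binary([[1, 0]], genes=["w", "x"])
        dts = [DTuple(genes=("w", "x"), state=(1, 1), phi=1, N=1, pi=0.2,
                      log2fc=1.0, p=0.01)]
        states = [
            s for s in assign_states(
                np.array([0]),
                CellByTupleMatrix(values=np.ones((1, 1), bool),
                                  tuple_index=dts, cell_ids=["c0"]),
            )
        ]
        proj = project_states(states, b2)
        assert proj["c0"] == set()  # x flipped: not a member

    def test_projection_missing_gene_listed(self, make_binary):
        b2 = make_binary([[1]], genes=["w"])
        dts = [DTuple(genes=("w", "x"), state=(1, 1), phi=1, N=1, pi=0.2,
                      log2fc=1.0, p=0.01)]
        states = assign_states(
            np.array([0]),
            CellByTupleMatrix(values=np.ones((1, 1), bool),
                              tuple_index=dts, cell_ids=["c0"]),
        )
        with pytest.raises(KeyError, match="x"):
            project_states(states, b2)
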