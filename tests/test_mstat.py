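"""M statistic: subtree scores, aggregation, fast-vs-naive oracle, permutation test."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from phylom import (
    TraitTable,
    bm_trait,
    m_statistic,
    m_statistic_naive,
    mix_continuous,
    permutation_test,
    read_newick,
    subtree_score,
    yule_tree,
)
from phylom.mstat import MEngine

from conftest import random_dm


def dm3(dab, dac, dbc):
    return DistanceMatrix(
        np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]], float),
        ids=["A", "B", "C"],
    )


class TestSubtreeScore:
    def test_two_vs_one_satisfied(self):
        s = subtree_score({"A", "B"}, {"C"}, dm3(0.2, 0.6, 0.4))
        assert s.d_first == pytest.approx(0.2)
        assert s.d_second == 0.0
        assert s.d_cross == pytest.approx(0.5)
        assert s.m == 1.0

    def test_first_branch_violated(self):
        s = subtree_score({"A", "B"}, {"C"}, dm3(0.9, 0.1, 0.1))
        assert s.d_cross == pytest.approx(0.1)
        assert s.m == 0.5  # single-tip branch always satisfies (0 <= d_cross)

    def test_all_equal_ties_satisfy(self):
        s = subtree_score({"A", "B"}, {"C"}, dm3(0.3, 0.3, 0.3))
        assert s.m == 1.0

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            subtree_score({"A", "B"}, {"B"}, dm3(0.1, 0.2, 0.3))

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            subtree_score({"A", "X"}, {"C"}, dm3(0.1, 0.2, 0.3))


class TestMStatistic:
    def test_three_tip_signal(self, three_tip_tree):
        assert m_statistic(three_tip_tree, dm3(0.1, 0.5, 0.7)) == 1.0

    def test_three_tip_antisignal(self, three_tip_tree):
        assert m_statistic(three_tip_tree, dm3(0.9, 0.2, 0.2)) == 0.5

    def test_patristic_gives_one(self, random_tree_factory):
        """Perfect-signal limit: the tree's own distances satisfy every subtree."""
        for seed in range(10):
            t = random_tree_factory(int(10 + 2 * seed), seed)
            dm = DistanceMatrix(t.patristic_matrix(), ids=list(t.tip_labels))
            assert m_statistic(t, dm) == 1.0

    def test_fast_equals_naive(self, random_tree_factory):
        rng = np.random.default_rng(42)
        for _ in range(20):
            t = random_tree_factory(int(rng.integers(5, 31)), int(rng.integers(1 << 30)))
            dm = random_dm(t, rng)
            assert m_statistic(t, dm) == m_statistic_naive(t, dm)

    def test_value_on_grid(self, random_tree_factory):
        # M is a mean of subtree scores in {0, 1/2, 1}: M in {k/(2n)}
        from phylom import decompose_subtrees

        rng = np.random.default_rng(7)
        t = random_tree_factory(16, 5)
        n = decompose_subtrees(t).n_subtrees
        for _ in range(5):
            m = m_statistic(t, random_dm(t, rng))
            assert 0.0 <= m <= 1.0
            k = m * 2 * n
            assert k == pytest.approx(round(k), abs=1e-9)

    def test_branch_length_invariance(self, random_tree_factory):
        rng = np.random.default_rng(11)
        for seed in range(5):
            t = random_tree_factory(14, seed)
            dm = random_dm(t, rng)
            scaled = type(t)(
                t.tip_labels, t.left_child, t.right_child, t.parent,
                t.branch_length * rng.uniform(0.1, 10),
            )
            assert m_statistic(t, dm) == m_statistic(scaled, dm)

    def test_label_permutation_equivariance(self, random_tree_factory):
        # consistently renaming species in tree and distances leaves M unchanged
        t = yule_tree(10, 0.05, seed=3)
        rng = np.random.default_rng(3)
        dm = random_dm(t, rng)
        mapping = {lbl: f"sp_{i}" for i, lbl in enumerate(t.tip_labels)}
        t2 = type(t)(
            tuple(mapping[x] for x in t.tip_labels),
            t.left_child, t.right_child, t.parent, t.branch_length,
        )
        dm2 = DistanceMatrix(dm.data, ids=[mapping[x] for x in dm.ids])
        assert m_statistic(t, dm) == m_statistic(t2, dm2)

    def test_missing_tip_distance_is_error(self, three_tip_tree):
        dm = DistanceMatrix(np.array([[0, 0.5], [0.5, 0]]), ids=["A", "B"])
        with pytest.raises(KeyError, match="prune"):
            m_statistic(three_tip_tree, dm)


class TestPermutationTest:
    @staticmethod
    def cont_table(trait):
        return TraitTable(trait.to_frame(), {"trait": "continuous"})

    def test_p_value_formula_and_reproducibility(self):
        t = yule_tree(30, 0.05, seed=1)
        trait = bm_trait(t, 0.01, 0.0, seed=2)
        res = permutation_test(t, self.cont_table(trait), n_perm=99, seed=5)
        expected_p = (1 + np.count_nonzero(res.null_m >= res.m_obs)) / 100.0
        assert res.p_value == pytest.approx(expected_p)
        res2 = permutation_test(t, self.cont_table(trait), n_perm=99, seed=5)
        assert res.m_obs == res2.m_obs
        np.testing.assert_array_equal(res.null_m, res2.null_m)

    def test_constant_trait_degenerates(self):
        t = yule_tree(30, 0.05, seed=4)
        trait = pd.Series(1.0, index=list(t.tip_labels), name="trait")
        with pytest.warns(UserWarning):
            res = permutation_test(t, self.cont_table(trait), n_perm=49, seed=0)
        assert res.m_obs == 1.0
        assert (res.null_m == 1.0).all()
        assert res.p_value == 1.0

    def test_strong_signal_detected(self):
        t = yule_tree(60, 0.05, seed=6)
        trait = bm_trait(t, 0.01, 0.0, seed=7)
        res = permutation_test(t, self.cont_table(trait), n_perm=199, seed=8)
        assert res.significant
        assert res.p_value <= 0.05

    def test_small_tree_warns(self):
        t = yule_tree(10, 0.05, seed=9)
        trait = bm_trait(t, 0.01, 0.0, seed=10)
        with pytest.warns(UserWarning, match="below the recommended minimum"):
            permutation_test(t, self.cont_table(trait), n_perm=9, seed=0)

    def test_prune_flag(self):
        t = yule_tree(30, 0.05, seed=11)
        trait = bm_trait(t, 0.01, 0.0, seed=12)
        extra = pd.concat(
            [trait, pd.Series([0.5], index=["ghost"], name="trait")]
        ).rename("trait")
        table = TraitTable(extra.to_frame(), {"trait": "continuous"})
        with pytest.raises(KeyError, match="prune"):
            permutation_test(t, table, n_perm=9, seed=0)
        with pytest.warns(UserWarning, match="pruning"):
            res = permutation_test(t, table, n_perm=9, seed=0, prune=True)
        assert res.n_species == 30

    def test_row_permutation_equals_matrix_permutation(self):
        """Permuting trait rows == jointly permuting rows+columns of D."""
        t = yule_tree(15, 0.05, seed=13)
        rng = np.random.default_rng(14)
        dm = random_dm(t, rng)
        eng = MEngine(t, labels=list(dm.ids))
        perm = rng.permutation(t.n_tips)
        via_perm_arg = eng.m(dm.data, perm=perm)
        shuffled = dm.data[np.ix_(perm, perm)]
        # tips keep their positions; row k of the shuffled matrix is old row perm[k]
        via_matrix = MEngine(t, labels=list(dm.ids)).m(shuffled)
        assert via_perm_arg == via_matrix

    def test_multi_trait_rows_move_jointly(self):
        # null replicates preserve trait-trait correlation: a duplicated column
        # yields the same null distribution as the single column
        t = yule_tree(20, 0.05, seed=15)
        trait = bm_trait(t, 0.01, 0.0, seed=16)
        single = TraitTable(trait.to_frame(), {"trait": "continuous"})
        double = TraitTable(
            pd.DataFrame({"a": trait, "b": trait}),
            {"a": "continuous", "b": "continuous"},
        )
        r1 = permutation_test(t, single, n_perm=49, seed=17)
        r2 = permutation_test(t, double, ["a", "b"], n_perm=49, seed=17)
        assert r1.m_obs == r2.m_obs
        np.testing.assert_array_equal(r1.null_m, r2.null_m)

    def test_result_serialization(self, tmp_path):
        t = yule_tree(25, 0.05, seed=18)
        trait = bm_trait(t, 0.01, 0.0, seed=19)
        res = permutation_test(t, self.cont_table(trait), n_perm=19, seed=20)
        d = res.to_dict()
        assert set(d) >= {"M", "p_value", "n_perm", "seed", "alpha",
                          "n_subtrees", "n_species", "columns"}
        path = tmp_path / "res.json"
        res.to_json(str(path))
        import json

        assert json.loads(path.read_text())["M"] == res.m_obs
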