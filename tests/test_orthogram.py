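import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cladesig.orthogram import (
    build_orthobasis,
    decompose_trait,
    orthogram_statistics,
    orthogram_test,
    significant_nodes,
)
from cladesig.synthetic import random_polytomy_tree, simulate_trait, simulate_tree
from cladesig.treeio import read_newick


class TestOrthobasis:
    def test_balanced_four_tip_columns(self, balanced4):
        b = build_orthobasis(balanced4)
        # root contrast: +-1/2 on the two cherries
        assert np.allclose(np.abs(b.vectors[:, 0]), 0.5)
        # cherry contrasts: +-1/sqrt(2) on two tips, zero elsewhere
        for j in (1, 2):
            col = b.vectors[:, j]
            assert np.allclose(sorted(np.abs(col)), [0, 0, 2**-0.5, 2**-0.5])

    def test_column_count_with_polytomies(self):
        t = read_newick("((A,B,C),(D,E),F);")
        b = build_orthobasis(t)
        assert b.vectors.shape == (6, 5)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            build_orthobasis(read_newick("(A,B);"))

    @given(seed=st.integers(0, 10_000), n=st.integers(3, 40))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_orthonormal_and_centered(self, seed, n):
        t = random_polytomy_tree(n, seed)
        b = build_orthobasis(t)
        B = b.vectors
        assert B.shape == (n, n - 1)
        assert np.abs(B.T @ B - np.eye(n - 1)).max() < 1e-10
        assert np.abs(B.sum(axis=0)).max() < 1e-10
        # column ordering follows decreasing node complexity
        assert (np.diff(b.np_of_column) <= 0).all()


class TestDecompose:
    def test_root_concentrated_trait(self, balanced4):
        b = build_orthobasis(balanced4)
        r2 = decompose_trait(np.array([1.0, 1.0, -1.0, -1.0]), b)
        assert np.allclose(r2, [1.0, 0.0, 0.0])

    def test_constant_trait_rejected(self, balanced4):
        b = build_orthobasis(balanced4)
        with pytest.raises(ValueError, match="constant"):
            decompose_trait(np.full(4, 3.14), b)

    def test_length_mismatch(self, balanced4):
        b = build_orthobasis(balanced4)
        with pytest.raises(ValueError, match="match"):
            decompose_trait(np.arange(5.0), b)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_parseval_and_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        t = random_polytomy_tree(rng.integers(3, 30), rng)
        b = build_orthobasis(t)
        x = rng.normal(size=t.n_tips)
        r2 = decompose_trait(x, b)
        assert r2.min() >= 0
        assert abs(r2.sum() - 1.0) < 1e-10
        # completeness: basis reconstructs the standardized trait exactly
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        assert np.abs(b.vectors @ (b.vectors.T @ xs) - xs).max() < 1e-10

    def test_per_node_r2_independent_of_basis_rotation(self):
        # a polytomy's columns are convention-dependent, but the summed R2
        # per node must match any orthonormal basis of the same subspaces
        t = read_newick("((A,B,C,D),(E,F),G);")
        b = build_orthobasis(t)
        rng = np.random.default_rng(5)
        x = rng.normal(size=t.n_tips)
        r2 = decompose_trait(x, b)
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        for v in t.children:
            cols = np.flatnonzero(b.node_of_column == v)
            sub = b.vectors[:, cols]
            q, _ = np.linalg.qr(sub @ rng.normal(size=(len(cols), len(cols))))
            assert np.isclose(r2[cols].sum(), ((q.T @ xs) ** 2).sum(), atol=1e-10)


class TestStatistics:
    def test_fully_concentrated_profile(self):
        stats = orthogram_statistics(np.array([1.0, 0.0, 0.0]))
        assert stats["R2Max"] == 1.0
        assert stats["SkR2k"] == 1.0
        assert np.isclose(stats["Dmax"], 2 / 3)
        assert np.isclose(stats["SCE"], 5 / 9)

    def test_uniform_profile_has_zero_deviation(self):
        stats = orthogram_statistics(np.full(3, 1 / 3))
        assert np.isclose(stats["Dmax"], 0.0)
        assert np.isclose(stats["SCE"], 0.0)

    def test_r2max_is_max(self):
        assert orthogram_statistics(np.array([0.5, 0.3, 0.2]))["R2Max"] == 0.5

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            orthogram_statistics(np.array([0.5, 0.2]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_statistic_ranges(self, seed):
        rng = np.random.default_rng(seed)
        r2 = rng.dirichlet(np.ones(rng.integers(2, 40)))
        stats = orthogram_statistics(r2)
        B = len(r2)
        assert 1 <= stats["SkR2k"] <= B
        assert 0 <= stats["Dmax"] < 1
        assert stats["SCE"] >= 0


class TestPermutationTest:
    def test_pvalues_in_unit_interval_and_reproducible(self, rng):
        t = simulate_tree(16, rng)
        x = simulate_trait(t, "brownian", 1.0, rng)
        a = orthogram_test(x, t, n_perm=199, seed=42)
        b = orthogram_test(x, t, n_perm=199, seed=42)
        for name, p in a.pvalues.items():
            assert 0 < p <= 1
            assert p == b.pvalues[name]
        assert np.array_equal(a.r2_upper_envelope, b.r2_upper_envelope)

    def test_invariant_to_joint_relabeling(self, rng):
        from cladesig.treeio import Tree

        t = simulate_tree(12, rng)
        x = simulate_trait(t, "brownian", 1.0, rng)
        res = orthogram_test(x, t, n_perm=199, seed=7)
        # relabel every tip; the trait stays attached to the same tip node
        t2 = Tree(
            root=t.root,
            children=dict(t.children),
            parent=dict(t.parent),
            tip_labels={tip: f"sp_{lab}" for tip, lab in t.tip_labels.items()},
        )
        res2 = orthogram_test(x, t2, n_perm=199, seed=7)
        assert res.pvalues == res2.pvalues

    def test_small_n_perm_rejected(self, balanced4):
        with pytest.raises(ValueError, match="n_perm"):
            orthogram_test(np.array([1.0, 2.0, 3.0, 4.0]), balanced4, n_perm=10, seed=0)

    def test_cumulative_monotone_ends_at_one(self, rng):
        t = simulate_tree(20, rng)
        x = simulate_trait(t, "white_noise", 1.0, rng)
        res = orthogram_test(x, t, n_perm=199, seed=1)
        assert (np.diff(res.cumulative) >= -1e-12).all()
        assert np.isclose(res.cumulative[-1], 1.0)


class TestSignificantNodes:
    def test_root_concentration_flags_root(self):
        # two clades of 8 tips with opposite values: all variance at the root
        newick = "(({}),({}));".format(
            ",".join(f"a{i}" for i in range(8)), ",".join(f"b{i}" for i in range(8))
        )
        t = read_newick(newick)
        x = np.array([1.0] * 8 + [-1.0] * 8)
        res = orthogram_test(x, t, n_perm=499, seed=3)
        flagged = significant_nodes(res)
        assert flagged and flagged[0][0] == t.root
        assert np.isclose(flagged[0][1], 1.0)

    def test_sorted_by_decreasing_r2(self, rng):
        t = simulate_tree(24, rng)
        x = simulate_trait(t, "brownian", 1.0, rng)
        flagged = significant_nodes(orthogram_test(x, t, n_perm=199, seed=9))
        values = [r for _, r in flagged]
        assert values == sorted(values, reverse=True)
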