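import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from cladesig.ancestral import fitch_optimize, reconstruct_landmarks
from cladesig.treeio import read_newick
from helpers import all_rooted_newicks, brute_fitch_steps


def brute_squared_optimum(tree, tip_values):
    """Numerical minimizer of the squared tree score (independent oracle)."""
    internal = list(tree.internal_nodes)
    flat = {tree.tip_of_label[l]: np.asarray(v, float).ravel() for l, v in tip_values.items()}
    d = len(next(iter(flat.values())))

    def score(vec):
        values = dict(flat)
        for i, v in enumerate(internal):
            values[v] = vec[i * d : (i + 1) * d]
        return sum(
            ((values[a] - values[b]) ** 2).sum()
            for a in tree.children
            for b in tree.children[a]
        )

    x0 = np.tile(np.mean(list(flat.values()), axis=0), len(internal))
    res = minimize(score, x0, method="BFGS", tol=1e-12)
    return res.fun, res.x.reshape(len(internal), d)


class TestSquaredChange:
    def test_identical_tips_give_zero_score(self, balanced4):
        cfg = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        tips = {lab: cfg for lab in balanced4.tip_order}
        for criterion in ("squared", "linear"):
            res = reconstruct_landmarks(balanced4, tips, criterion=criterion)
            assert res.tree_score < 1e-18
            for shape in res.node_configs.values():
                assert np.allclose(shape, cfg)

    def test_three_tip_star_mean(self):
        t = read_newick("(A,B,C);")
        res = reconstruct_landmarks(t, {"A": [[0.0]], "B": [[0.0]], "C": [[3.0]]})
        assert np.isclose(res.node_configs[t.root][0, 0], 1.0)
        assert np.isclose(res.tree_score, 6.0)

    def test_caterpillar_hand_solution(self, caterpillar3):
        res = reconstruct_landmarks(
            caterpillar3, {"A": [[0.0]], "B": [[0.0]], "C": [[3.0]]}
        )
        inner = [v for v in caterpillar3.children if v != caterpillar3.root][0]
        assert np.isclose(res.node_configs[inner][0, 0], 0.6)
        assert np.isclose(res.node_configs[caterpillar3.root][0, 0], 1.8)
        assert np.isclose(res.tree_score, 3.6)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_numerical_minimizer_on_all_topologies(self, n):
        rng = np.random.default_rng(n)
        for newick in all_rooted_newicks(n):
            t = read_newick(newick)
            tips = {lab: rng.normal(size=(2, 2)) for lab in t.tip_order}
            res = reconstruct_landmarks(t, tips)
            brute_score, _ = brute_squared_optimum(t, tips)
            assert abs(res.tree_score - brute_score) < 1e-4, newick

    def test_score_invariant_under_rigid_motion(self, rng):
        t = read_newick("((A,B),(C,(D,E)));")
        tips = {lab: rng.normal(size=(4, 2)) for lab in t.tip_order}
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = {lab: v @ rot.T + np.array([2.0, -1.0]) for lab, v in tips.items()}
        s1 = reconstruct_landmarks(t, tips).tree_score
        s2 = reconstruct_landmarks(t, moved).tree_score
        assert np.isclose(s1, s2)

    def test_missing_tip_rejected(self, caterpillar3):
        with pytest.raises(ValueError, match="missing"):
            reconstruct_landmarks(caterpillar3, {"A": [[0.0]], "B": [[0.0]]})

    def test_shape_mismatch_rejected(self, caterpillar3):
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct_landmarks(
                caterpillar3, {"A": [[0.0]], "B": [[0.0]], "C": [[3.0, 1.0]]}
            )


class TestLinearCriterion:
    def test_linear_improves_on_squared_start(self, rng):
        t = read_newick("(((A,B),C),(D,E));")
        tips = {lab: rng.normal(size=(3, 2)) for lab in t.tip_order}
        sq = reconstruct_landmarks(t, tips, criterion="squared")
        lin = reconstruct_landmarks(t, tips, criterion="linear")
        # evaluate both solutions under the linear score
        def linear_score(configs):
            values = {tree_tip: tips[lab] for lab, tree_tip in
                      ((l, t.tip_of_label[l]) for l in t.tip_order)}
            values = {k: np.asarray(v, float) for k, v in values.items()}
            values.update(configs)
            return sum(
                np.linalg.norm(values[a] - values[b])
                for a in t.children
                for b in t.children[a]
            )

        assert lin.tree_score <= linear_score(sq.node_configs) + 1e-9
        assert np.isclose(lin.tree_score, linear_score(lin.node_configs))


class TestFitch:
    def test_uniform_states_need_no_steps(self, balanced4):
        res = fitch_optimize(balanced4, {lab: 0 for lab in balanced4.tip_order})
        assert res.steps == 0
        assert set(res.assignment.values()) == {0}

    def test_two_clades_one_step(self, balanced4):
        res = fitch_optimize(balanced4, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert res.steps == 1

    def test_alternating_two_steps(self, balanced4):
        res = fitch_optimize(balanced4, {"A": 0, "B": 1, "C": 0, "D": 1})
        assert res.steps == 2

    def test_unscored_tip_rejected(self, balanced4):
        with pytest.raises(ValueError, match="unscored"):
            fitch_optimize(balanced4, {"A": 0, "B": 1})

    @pytest.mark.parametrize("n", [3, 4])
    def test_steps_match_enumeration_all_trees_all_states(self, n):
        for newick in all_rooted_newicks(n):
            t = read_newick(newick)
            for combo in itertools.product((0, 1), repeat=n):
                states = dict(zip(t.tip_order, combo))
                res = fitch_optimize(t, states)
                assert res.steps == brute_fitch_steps(t, states), (newick, combo)

    @pytest.mark.parametrize("n", [5, 6])
    def test_steps_match_enumeration_sampled_states(self, n):
        rng = np.random.default_rng(n)
        newicks = all_rooted_newicks(n)
        for newick in rng.choice(newicks, size=60, replace=False):
            t = read_newick(newick)
            states = dict(zip(t.tip_order, rng.integers(0, 2, size=n)))
            res = fitch_optimize(t, states)
            assert res.steps == brute_fitch_steps(t, states), newick

    def test_assignment_cost_equals_steps(self, rng):
        for newick in rng.choice(all_rooted_newicks(6), size=40, replace=False):
            t = read_newick(newick)
            states = dict(zip(t.tip_order, rng.integers(0, 2, size=6)))
            res = fitch_optimize(t, states)
            cost = sum(
                res.assignment[v] != res.assignment[k]
                for v in t.children
                for k in t.children[v]
            )
            assert cost == res.steps
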