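"""Exact alpha-vector value iteration: backups, pruning, value extraction."""

import numpy as np
import pytest

from ecopomdp import (
    AlphaSet,
    AlphaVector,
    backcast,
    backup,
    backup_extended,
    backward_induction,
    belief_partition,
    extract_policy_tree,
    prune,
    solve_finite_pomdp,
    solve_infinite_pomdp,
    stage_value_from_backcasts,
    terminal_alpha_set,
    value_at,
)
from ecopomdp.alpha_solver import belief_grid, values_on_grid
from ecopomdp.model_core import DecisionProcessSpec, EXTENDED
from conftest import exact_pomdp_values, random_spec


class TestTerminalSet:
    def test_nuisance_returns_prune_a3(self, nuisance_pomdp):
        L = terminal_alpha_set(nuisance_pomdp)
        assert [v.components.tolist() for v in L.vectors] == [
            [14.5, 5.0],
            [12.0, 7.5],
        ]
        # the two surviving return lines cross at b = 0.5
        v1, v2 = L.vectors
        b_cross = (v2.components[1] - v1.components[1]) / (
            (v1.components[0] - v1.components[1]) - (v2.components[0] - v2.components[1])
        )
        assert b_cross == pytest.approx(0.5)

    def test_single_action_singleton(self, nuisance_pomdp):
        spec = nuisance_pomdp.replace(
            action_labels=("a1",),
            transitions=nuisance_pomdp.transitions[:1],
            returns=nuisance_pomdp.returns[:1],
            observations=nuisance_pomdp.observations[:1],
        )
        L = terminal_alpha_set(spec)
        assert len(L) == 1 and np.allclose(L.vectors[0].components, [14.5, 5.0])

    def test_two_action_fixture_crossing(self, backcast_fixture):
        """The two return lines 7.9-5.6b and 2.5+5.6b cross at b = 27/56,
        where both equal 5.2."""
        spec_like = AlphaSet(
            [AlphaVector(backcast_fixture.returns[a], a) for a in range(2)]
        )
        L = prune(spec_like)
        assert len(L) == 2
        b = 27 / 56
        vals = L.matrix @ np.array([b, 1 - b])
        assert vals[0] == pytest.approx(vals[1])
        assert vals[0] == pytest.approx(5.2)
        assert round(b, 1) == 0.5


class TestBackcast:
    def test_hand_arithmetic(self, nuisance_pomdp):
        g = backcast(np.array([14.5, 5.0]), "a1", "o1", nuisance_pomdp)
        assert g == pytest.approx([2.185, 2.5])

    def test_linearity_zero_vector(self, nuisance_pomdp):
        assert backcast(np.zeros(2), "a2", "o2", nuisance_pomdp) == pytest.approx([0, 0])

    def test_one_state_scalar(self):
        spec = DecisionProcessSpec(
            ("s",), ("a",), [[[1.0]]], [[2.0]],
            observation_labels=("o",), observations=[[[1.0]]],
        )
        assert backcast(np.array([3.0]), 0, 0, spec) == pytest.approx([3.0])


class TestPrune:
    def test_pointwise_dominance(self):
        L = AlphaSet([AlphaVector([12, 7.5], 1), AlphaVector([10, 5.5], 2)])
        out = prune(L)
        assert len(out) == 1 and np.allclose(out.vectors[0].components, [12, 7.5])

    def test_witness_dominated_interior_vector(self):
        L = AlphaSet(
            [AlphaVector([10, 0], 0), AlphaVector([0, 10], 1), AlphaVector([4.9, 4.9], 2)]
        )
        out = prune(L)
        assert sorted(v.components[0] for v in out.vectors) == [0, 10]

    def test_singleton_unchanged(self):
        L = AlphaSet([AlphaVector([1.0, 2.0], 0)])
        assert len(prune(L)) == 1

    def test_empty_input(self):
        assert len(prune(AlphaSet([]))) == 0

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("n_states", [2, 3, 4])
    def test_envelope_preserved_on_grid(self, seed, n_states):
        """Pruning never changes the max-over-vectors value (1,001-point
        lattice, 1e-12)."""
        rng = np.random.default_rng(300 + seed)
        vecs = [
            AlphaVector(rng.uniform(0, 10, n_states), int(rng.integers(3)))
            for _ in range(25)
        ]
        L = AlphaSet(vecs)
        grid = belief_grid(n_states, 1001 if n_states == 2 else 33)
        before = values_on_grid(L, grid)
        after = values_on_grid(prune(L), grid)
        assert np.max(np.abs(before - after)) < 1e-12


class TestValueAt:
    def test_vertex_values_and_tie(self, nuisance_pomdp):
        L = terminal_alpha_set(nuisance_pomdp)
        v, a, _ = value_at([1.0, 0.0], L)
        assert (v, a) == (14.5, 0)
        v, a, _ = value_at([0.0, 1.0], L)
        assert (v, a) == (7.5, 1)
        v, a, _ = value_at([0.5, 0.5], L)
        assert v == pytest.approx(9.75)
        assert a == 0  # tie resolved to the lowest action index

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            value_at([1.0], AlphaSet([]))


class TestStageValueFromBackcasts:
    def test_vertex_b1(self, backcast_fixture):
        v, a = stage_value_from_backcasts(
            1.0, backcast_fixture.returns, backcast_fixture.lines, 0.9,
            backcast_fixture.action_labels, backcast_fixture.observation_labels,
        )
        assert v == pytest.approx(27.99)
        assert a == "a2"

    def test_vertex_b0(self, backcast_fixture):
        v, a = stage_value_from_backcasts(
            0.0, backcast_fixture.returns, backcast_fixture.lines, 0.9,
            backcast_fixture.action_labels, backcast_fixture.observation_labels,
        )
        assert v == pytest.approx(26.08)
        assert a == "a1"

    def test_zero_discount_is_immediate_return(self, backcast_fixture):
        v, a = stage_value_from_backcasts(
            1.0, backcast_fixture.returns, backcast_fixture.lines, 0.0,
            backcast_fixture.action_labels, backcast_fixture.observation_labels,
        )
        assert (v, a) == (pytest.approx(8.1), "a2")

    def test_missing_line_raises(self, backcast_fixture):
        lines = dict(backcast_fixture.lines)
        del lines[("a2", "a2", "o3")]
        with pytest.raises(KeyError, match="a2"):
            stage_value_from_backcasts(
                0.5, backcast_fixture.returns, lines, 0.9,
                backcast_fixture.action_labels, backcast_fixture.observation_labels,
            )


class TestBackup:
    def test_single_observation_is_open_loop(self, nuisance_mdp):
        """With |O| = 1 there is no branching: each backup applies the MDP
        Bellman operator to one alpha-vector at a time, so the process is
        open-loop.  Values match the exact no-information recursion and are
        bounded above by the fully observable MDP (value of information)."""
        spec = nuisance_mdp.replace(
            observation_labels=("o",), observations=np.ones((2, 1))
        )
        sets = solve_finite_pomdp(spec, horizon=3)
        table = backward_induction(nuisance_mdp, horizon=3)
        B = np.vstack([np.eye(2), [[0.5, 0.5]]])
        for k, L in enumerate(sets):
            expected = exact_pomdp_values(spec, B, k + 1)
            got = np.array([value_at(b, L)[0] for b in B])
            assert got == pytest.approx(expected, abs=1e-10)
            for x in range(2):
                assert value_at(np.eye(2)[x], L)[0] <= table.values[k, x] + 1e-10
        # terminal epoch carries no future term, so vertices agree exactly
        assert value_at([1, 0], sets[0])[0] == table.values[0, 0]

    def test_single_observation_deterministic_transitions_match_mdp(self):
        """When transitions are deterministic a degenerate belief stays
        degenerate, so even the no-information process equals the MDP at
        vertex beliefs."""
        P = np.array([[[0, 1.0], [1.0, 0]], [[1.0, 0], [1.0, 0]]])
        R = np.array([[3.0, 1.0], [0.0, 2.0]])
        mdp = DecisionProcessSpec(("x1", "x2"), ("a1", "a2"), P, R,
                                  discount=0.9, horizon=4)
        pomdp = mdp.replace(observation_labels=("o",),
                            observations=np.ones((2, 1)))
        sets = solve_finite_pomdp(pomdp)
        table = backward_induction(mdp)
        for k, L in enumerate(sets):
            for x in range(2):
                assert value_at(np.eye(2)[x], L)[0] == pytest.approx(
                    table.values[k, x], abs=1e-10
                )

    def test_perfect_observation_matches_mdp_at_vertices(self, nuisance_mdp):
        """A POMDP whose monitoring reveals the state reproduces the MDP
        values (the printed three-epoch table) at vertex beliefs."""
        spec = nuisance_mdp.replace(
            observation_labels=("o1", "o2"), observations=np.eye(2)
        )
        sets = solve_finite_pomdp(spec, horizon=3)
        table = backward_induction(nuisance_mdp, horizon=3)
        for k, L in enumerate(sets):
            for x in range(2):
                v, a, _ = value_at(np.eye(2)[x], L)
                assert v == pytest.approx(table.values[k, x], abs=1e-10)
                assert a == table.actions[k, x]

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_recursion_oracle_random_specs(self, seed):
        """Alpha-vector values equal direct recursive evaluation of the
        optimal value at random beliefs, for 20 random small POMDPs."""
        rng = np.random.default_rng(1000 + seed)
        nx = int(rng.integers(2, 4))
        na = int(rng.integers(2, 4))
        no = int(rng.integers(2, 4))
        h = int(rng.integers(2, 5))
        spec = random_spec(rng, nx, na, no, horizon=h)
        sets = solve_finite_pomdp(spec)
        B = rng.dirichlet(np.ones(nx), size=12)
        expected = exact_pomdp_values(spec, B, h)
        got = np.array([value_at(b, sets[-1])[0] for b in B])
        assert got == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_value_function_is_convex(self, seed):
        """Midpoint inequality on random belief pairs."""
        rng = np.random.default_rng(2000 + seed)
        spec = random_spec(rng, 3, 2, 2, horizon=3)
        L = solve_finite_pomdp(spec)[-1]
        for _ in range(50):
            b1, b2 = rng.dirichlet(np.ones(3), size=2)
            mid = 0.5 * (b1 + b2)
            assert (
                value_at(mid, L)[0]
                <= 0.5 * value_at(b1, L)[0] + 0.5 * value_at(b2, L)[0] + 1e-10
            )

    def test_informative_observations_never_hurt(self, nuisance_pomdp):
        """Value with the monitoring model dominates the value with an
        uninformative observation model at every tested belief."""
        blind = nuisance_pomdp.replace(observations=np.full((2, 3), 1 / 3))
        L_obs = solve_finite_pomdp(nuisance_pomdp, horizon=4)[-1]
        L_blind = solve_finite_pomdp(blind, horizon=4)[-1]
        grid = belief_grid(2, 101)
        assert np.all(
            values_on_grid(L_obs, grid) >= values_on_grid(L_blind, grid) - 1e-9
        )

    def test_candidate_cap_guard(self, nuisance_pomdp):
        L = terminal_alpha_set(nuisance_pomdp)
        with pytest.raises(MemoryError, match="cap"):
            backup(L, nuisance_pomdp, cap=3)


class TestInfiniteHorizon:
    def test_zero_discount_stops_after_terminal(self, nuisance_pomdp):
        sol = solve_infinite_pomdp(nuisance_pomdp.replace(discount=1e-9))
        assert sol.iterations <= 1

    def test_bellman_residual_small(self, nuisance_pomdp, stationary_pomdp_solution):
        """One extra backup changes the converged envelope by less than the
        stopping tolerance scaled through the contraction."""
        L = stationary_pomdp_solution.alpha_set
        grid = belief_grid(2, 1001)
        before = values_on_grid(L, grid)
        after = values_on_grid(backup(L, nuisance_pomdp), grid)
        assert np.max(np.abs(after - before)) < 1e-5
        assert stationary_pomdp_solution.error_bound < 1e-4

    def test_partition_structure(self, nuisance_pomdp, stationary_pomdp_solution):
        segs = belief_partition(stationary_pomdp_solution.alpha_set, nuisance_pomdp)
        assert segs[0]["b_low"] == 0.0 and segs[-1]["b_high"] == 1.0
        for s1, s2 in zip(segs, segs[1:]):
            assert s2["b_low"] > s1["b_low"]


class TestExtendedBackup:
    def test_uninformative_matches_standard_no_information(self, nuisance_mdp):
        """When the observation carries no information and transitions do
        not depend on it, timing cannot matter."""
        f_uniform = np.full((2, 2), 0.5)
        std = nuisance_mdp.replace(
            observation_labels=("o1", "o2"), observations=f_uniform
        )
        ext = std.replace(timing=EXTENDED)
        L_std = solve_finite_pomdp(std, horizon=3)[-1]
        L_ext = solve_finite_pomdp(ext, horizon=3)[-1]
        grid = belief_grid(2, 101)
        assert values_on_grid(L_std, grid) == pytest.approx(
            values_on_grid(L_ext, grid), abs=1e-10
        )

    def test_identity_prior_observation_against_delayed_info_oracle(self, nuisance_mdp):
        """When o reveals the prior state, the information arrives one step
        late (the observation follows the action).  The solved values must
        match an independent recursive evaluation of the extended-timing
        optimal value, and fall between the no-information process and the
        fully observable MDP."""
        ext = nuisance_mdp.replace(
            observation_labels=("o1", "o2"), observations=np.eye(2), timing=EXTENDED
        )

        def oracle(b, steps):
            b = np.asarray(b, float)
            if steps == 1:
                return (ext.returns @ b).max()
            best = -np.inf
            for a in range(ext.n_actions):
                val = b @ ext.returns[a]
                acc = 0.0
                for o in range(2):
                    lik = float(ext.observations[a][:, o] @ b)
                    if lik > 1e-14:
                        post = (b * ext.observations[a][:, o]) @ ext.transitions[a] / lik
                        acc += lik * oracle(post, steps - 1)
                best = max(best, val + ext.discount * acc)
            return best

        sets = solve_finite_pomdp(ext, horizon=3)
        table = backward_induction(nuisance_mdp, horizon=3)
        rng = np.random.default_rng(5)
        beliefs = np.vstack([np.eye(2), rng.dirichlet(np.ones(2), size=5)])
        for k, L in enumerate(sets):
            for b in beliefs:
                assert value_at(b, L)[0] == pytest.approx(oracle(b, k + 1), abs=1e-10)
            for x in range(2):
                assert value_at(np.eye(2)[x], L)[0] <= table.values[k, x] + 1e-10

    def test_identity_prior_observation_deterministic_transitions_match_mdp(self):
        """With deterministic transitions the one-step delay in state
        information is harmless, and vertex values equal an MDP's."""
        P = np.array([[[0, 1.0], [1.0, 0]], [[1.0, 0], [1.0, 0]]])
        R = np.array([[3.0, 1.0], [0.0, 2.0]])
        mdp = DecisionProcessSpec(("x1", "x2"), ("a1", "a2"), P, R,
                                  discount=0.9, horizon=4)
        ext = mdp.replace(observation_labels=("o1", "o2"),
                          observations=np.eye(2), timing=EXTENDED)
        sets = solve_finite_pomdp(ext)
        table = backward_induction(mdp)
        for k, L in enumerate(sets):
            for x in range(2):
                assert value_at(np.eye(2)[x], L)[0] == pytest.approx(
                    table.values[k, x], abs=1e-10
                )

    def test_hand_example_one_step(self):
        """Two-state extended model propagated one step by hand.

        f(o1|x) = (0.8, 0.2); o1 keeps the state, o2 swaps it; a single
        action with returns (1, 0) and discount 1.  The one-step value at
        b is b*(R + sum_o f(o|x) g_o(x)) with g from the successor set.
        """
        P = np.array([[[[1.0, 0.0], [0.0, 1.0]], [[0.0, 1.0], [1.0, 0.0]]]])
        spec = DecisionProcessSpec(
            ("x1", "x2"), ("a1",), P, [[1.0, 0.0]],
            discount=1.0, horizon=2,
            observation_labels=("o1", "o2"),
            observations=[[0.8, 0.2], [0.2, 0.8]],
            timing=EXTENDED,
        )
        L1 = terminal_alpha_set(spec)  # single vector (1, 0)
        L0 = backup_extended(L1, spec)
        # by hand: g(x) = R(x) + f(o1|x)*[P_o1 (1,0)](x) + f(o2|x)*[P_o2 (1,0)](x)
        #   x1: 1 + 0.8*1 + 0.2*0 = 1.8 ; x2: 0 + 0.2*0 + 0.8*1 = 0.8
        assert len(L0) == 1
        assert L0.vectors[0].components == pytest.approx([1.8, 0.8])


class TestPolicyExtraction:
    def test_tree_structure_and_root(self, nuisance_pomdp):
        sets = solve_finite_pomdp(nuisance_pomdp, horizon=3)
        tree = extract_policy_tree(sets, [0.5, 0.5], nuisance_pomdp)
        tree.check(nuisance_pomdp.observation_labels)
        assert tree.depth == 3
        assert tree.root_action in nuisance_pomdp.action_labels
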