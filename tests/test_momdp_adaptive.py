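"""Mixed observability, hidden-model MDPs and adaptive management."""

import numpy as np
import pytest

from ecopomdp import (
    DecisionProcessSpec,
    ModelSet,
    backward_induction,
    hmmdp_solve,
    mixture_transition,
    model_belief_update,
    momdp_compose,
    nonstationary_belief_update,
    solve_finite_pomdp,
    update_standard,
    value_at,
)
from conftest import random_spec


@pytest.fixture
def two_models():
    """Two hypotheses about a 2-state, 2-action system: under y1 habitat
    alteration works well; under y2 it barely works."""
    P_y1 = [[[0.8, 0.2], [0.6, 0.4]], [[0.9, 0.1], [0.8, 0.2]]]
    P_y2 = [[[0.4, 0.6], [0.1, 0.9]], [[0.5, 0.5], [0.2, 0.8]]]
    return ModelSet(("y1", "y2"), np.array([P_y1, P_y2]))


@pytest.fixture
def hm_spec():
    return DecisionProcessSpec(
        ("x1", "x2"),
        ("a1", "a2"),
        [[[0.6, 0.4], [0.35, 0.65]], [[0.7, 0.3], [0.5, 0.5]]],
        [[10.0, 2.0], [8.0, 4.0]],
        discount=0.9,
        horizon=6,
    )


class TestMixtureTransition:
    def test_arithmetic_mean(self):
        models = ModelSet(
            ("y1", "y2"),
            np.array([[[[0.8, 0.2], [0.5, 0.5]]], [[[0.4, 0.6], [0.5, 0.5]]]]),
        )
        row = mixture_transition(0, 0, [0.5, 0.5], models)
        assert row == pytest.approx([0.6, 0.4])

    def test_degenerate_belief_selects_model(self, two_models):
        row = mixture_transition(1, 0, [0.0, 1.0], two_models)
        assert row == pytest.approx([0.1, 0.9])

    def test_identical_models_ignore_belief(self):
        P = np.array([[[0.7, 0.3], [0.2, 0.8]]])
        models = ModelSet(("y1", "y2"), np.array([P, P]))
        for w in ([1, 0], [0.3, 0.7], [0.5, 0.5]):
            assert mixture_transition(0, 0, w, models) == pytest.approx([0.7, 0.3])


class TestModelBeliefUpdate:
    def test_bayes_weighting(self):
        models = ModelSet(
            ("y1", "y2"),
            np.array([[[[0.8, 0.2], [0.5, 0.5]]], [[[0.4, 0.6], [0.5, 0.5]]]]),
        )
        post = model_belief_update([0.5, 0.5], 0, 0, 0, models)
        assert post.probabilities == pytest.approx([2 / 3, 1 / 3])

    def test_equal_likelihoods_leave_belief(self, two_models):
        # transition x2 -> x1 under a2 has likelihoods 0.8 vs 0.2
        b = [0.4, 0.6]
        post = model_belief_update(b, 0, 0, 0, two_models)
        lik = two_models.transitions[:, 0, 0, 0]
        expected = np.array(b) * lik / (np.array(b) @ lik)
        assert post.probabilities == pytest.approx(expected)

    def test_falsification(self):
        models = ModelSet(
            ("y1", "y2"),
            np.array([[[[0.8, 0.2], [0.5, 0.5]]], [[[1.0, 0.0], [0.5, 0.5]]]]),
        )
        post = model_belief_update([0.5, 0.5], 0, 0, 1, models)
        assert post.probabilities == pytest.approx([1.0, 0.0])

    def test_impossible_transition_raises(self):
        models = ModelSet(
            ("y1", "y2"),
            np.array([[[[1.0, 0.0], [0.5, 0.5]]], [[[1.0, 0.0], [0.5, 0.5]]]]),
        )
        with pytest.raises(ValueError, match="impossible"):
            model_belief_update([0.5, 0.5], 0, 0, 1, models)

    @pytest.mark.parametrize("b0", [[0.5, 0.5], [0.2, 0.8]])
    def test_martingale_property(self, two_models, b0):
        """Under data generated from the mixture, the expected posterior
        equals the prior (model beliefs are a martingale)."""
        rng = np.random.default_rng(42)
        n = 4000
        mix_row = mixture_transition(0, 0, b0, two_models)
        x_next = rng.choice(2, size=n, p=mix_row)
        posts = np.array(
            [model_belief_update(b0, 0, 0, x, two_models).probabilities for x in x_next]
        )
        mean = posts.mean(axis=0)
        se = posts.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(mean - b0) <= 3 * se + 1e-12)


class TestNonstationaryUpdate:
    def test_identity_model_transition_reduces_to_stationary(self, two_models):
        models_ns = ModelSet(
            two_models.model_labels, two_models.transitions, model_transition=np.eye(2)
        )
        b = [0.3, 0.7]
        prior_post, next_post = nonstationary_belief_update(b, 0, 1, 1, models_ns)
        stationary = model_belief_update(b, 0, 1, 1, two_models)
        assert prior_post.probabilities == pytest.approx(stationary.probabilities)
        assert next_post.probabilities == pytest.approx(stationary.probabilities)

    def test_uniform_likelihoods_propagate_through_model_transition(self):
        P = np.array([[[0.7, 0.3], [0.2, 0.8]]])
        M = np.array([[0.9, 0.1], [0.0, 1.0]])
        models = ModelSet(("y1", "y2"), np.array([P, P]), model_transition=M)
        b = np.array([0.6, 0.4])
        prior_post, next_post = nonstationary_belief_update(b, 0, 0, 0, models)
        assert prior_post.probabilities == pytest.approx(b)
        assert next_post.probabilities == pytest.approx(b @ M)

    def test_against_joint_enumeration_oracle(self, two_models):
        """Brute-force the joint distribution over (y, y') given the
        observed transition and compare both marginals."""
        M = np.array([[0.9, 0.1], [0.0, 1.0]])
        models = ModelSet(
            two_models.model_labels, two_models.transitions, model_transition=M
        )
        b = np.array([0.45, 0.55])
        x, a, xn = 0, 1, 1
        joint = np.zeros((2, 2))
        for y in range(2):
            for yn in range(2):
                joint[y, yn] = b[y] * M[y, yn] * models.transitions[yn, a, x, xn]
        joint /= joint.sum()
        prior_post, next_post = nonstationary_belief_update(b, x, a, xn, models)
        assert prior_post.probabilities == pytest.approx(joint.sum(axis=1))
        assert next_post.probabilities == pytest.approx(joint.sum(axis=0))


class TestHmmdpSolve:
    def test_single_model_equals_plain_mdp(self, hm_spec):
        models = ModelSet(("y1",), hm_spec.transitions[None, ...])
        sol = hmmdp_solve(hm_spec, models, grid_resolution=1.0)
        table = backward_induction(hm_spec)
        assert sol.values[:, 0] == pytest.approx(table.values[-1], abs=1e-9)

    def test_identical_models_constant_over_grid(self, hm_spec):
        models = ModelSet(
            ("y1", "y2"), np.stack([hm_spec.transitions, hm_spec.transitions])
        )
        sol = hmmdp_solve(hm_spec, models, grid_resolution=0.1)
        table = backward_induction(hm_spec)
        for g in range(len(sol.grid)):
            assert sol.values[:, g] == pytest.approx(table.values[-1], abs=1e-9)

    def test_value_monotone_in_favorable_model_weight(self, hm_spec, two_models):
        """y1 keeps abundance low more often, so value rises with the
        probability assigned to y1."""
        sol = hmmdp_solve(hm_spec, two_models, grid_resolution=0.1)
        order = np.argsort(sol.grid[:, 0])  # increasing weight on y1
        for x in range(2):
            diffs = np.diff(sol.values[x, order])
            assert np.all(diffs >= -1e-9)

    def test_grid_refinement_is_cauchy(self, hm_spec, two_models):
        """Values at shared nodes change less with each grid halving."""
        vals = {}
        for res in (0.2, 0.1, 0.05):
            sol = hmmdp_solve(hm_spec, two_models, grid_resolution=res)
            coarse_nodes = np.linspace(0, 1, 6)
            idx = [int(np.argmin(np.abs(sol.grid[:, 0] - c))) for c in coarse_nodes]
            vals[res] = sol.values[:, idx]
        d1 = np.max(np.abs(vals[0.1] - vals[0.2]))
        d2 = np.max(np.abs(vals[0.05] - vals[0.1]))
        assert d2 <= d1 + 1e-9

    def test_nonstationary_models_rejected(self, hm_spec, two_models):
        models = ModelSet(
            two_models.model_labels, two_models.transitions, model_transition=np.eye(2)
        )
        with pytest.raises(ValueError, match="stationary"):
            hmmdp_solve(hm_spec, models)


class TestMomdpCompose:
    def test_no_hidden_component_returns_mdp(self, nuisance_mdp):
        assert momdp_compose(nuisance_mdp, None) is nuisance_mdp

    def test_no_observable_component_returns_pomdp(self, nuisance_pomdp):
        assert momdp_compose(None, nuisance_pomdp) is nuisance_pomdp

    def test_product_belief_respects_observed_component(self):
        rng = np.random.default_rng(11)
        obs = random_spec(rng, 2, 2, None, discount=0.9)
        hid = random_spec(rng, 2, 2, 2, discount=0.9)
        prod = momdp_compose(obs, hid)
        assert prod.n_states == 4 and prod.n_observations == 4
        # one update: observing (x1, oy) must leave belief mass only on
        # product states whose observable component is x1
        b0 = np.full(4, 0.25)
        res = update_standard(b0, 0, 0, prod)  # observation "x0|o0"
        mass_on_x0 = res.posterior.probabilities[:2].sum()
        assert mass_on_x0 == pytest.approx(1.0)

    def test_perfectly_observable_hidden_component_reproduces_product_mdp(self):
        """If the hidden component is also perfectly observed, solving the
        composed POMDP equals backward induction on the product MDP at
        vertex beliefs."""
        rng = np.random.default_rng(12)
        obs = random_spec(rng, 2, 2, None, discount=0.8, horizon=3)
        hid = random_spec(rng, 2, 2, None, discount=0.8, horizon=3).replace(
            observation_labels=("oy1", "oy2"), observations=np.eye(2)
        )
        prod = momdp_compose(obs, hid)
        product_mdp = prod.replace(observation_labels=None, observations=None)
        sets = solve_finite_pomdp(prod, horizon=3)
        table = backward_induction(product_mdp, horizon=3)
        for k, L in enumerate(sets):
            for s in range(4):
                b = np.eye(4)[s]
                assert value_at(b, L)[0] == pytest.approx(table.values[k, s], abs=1e-8)

    def test_incompatible_actions_rejected(self, nuisance_mdp, nuisance_pomdp):
        hid = nuisance_pomdp.replace(action_labels=("u1", "u2", "u3"))
        with pytest.raises(ValueError, match="action"):
            momdp_compose(nuisance_mdp, hid)
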