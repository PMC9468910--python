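"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ecopomdp import builtin_example
from ecopomdp.model_core import DecisionProcessSpec, INFINITE


@pytest.fixture(scope="session")
def nuisance_mdp():
    return builtin_example("nuisance_mdp")


@pytest.fixture(scope="session")
def nuisance_pomdp():
    return builtin_example("nuisance_obs_pomdp")


@pytest.fixture(scope="session")
def backcast_fixture():
    return builtin_example("two_action_backcast_fixture")


@pytest.fixture(scope="session")
def stationary_pomdp_solution(nuisance_pomdp):
    """Infinite-horizon alpha-set for the monitored nuisance-species model
    (shared across tests; the solve is the expensive step)."""
    from ecopomdp import solve_infinite_pomdp

    return solve_infinite_pomdp(nuisance_pomdp, epsilon=1e-6)


def random_spec(
    rng: np.random.Generator,
    n_states: int,
    n_actions: int,
    n_observations: int | None,
    discount: float | None = None,
    horizon=INFINITE,
) -> DecisionProcessSpec:
    """A random dense (PO)MDP with Dirichlet-stochastic rows."""
    P = rng.dirichlet(np.ones(n_states), size=(n_actions, n_states))
    R = rng.uniform(0, 10, size=(n_actions, n_states))
    obs_labels = None
    F = None
    if n_observations:
        obs_labels = tuple(f"o{i}" for i in range(n_observations))
        F = rng.dirichlet(np.ones(n_observations), size=(n_actions, n_states))
    return DecisionProcessSpec(
        state_labels=tuple(f"x{i}" for i in range(n_states)),
        action_labels=tuple(f"a{i}" for i in range(n_actions)),
        transitions=P,
        returns=R,
        discount=rng.uniform(0.5, 0.95) if discount is None else discount,
        horizon=horizon,
        observation_labels=obs_labels,
        observations=F,
    )


def exact_pomdp_values(spec: DecisionProcessSpec, beliefs: np.ndarray, steps: int
                       ) -> np.ndarray:
    """Independent oracle: exact optimal POMDP value at each belief by direct
    recursion over the (action, observation) tree — no alpha-vectors.

    ``beliefs`` is (n, |X|); ``steps`` counts decision epochs including the
    terminal one.  Standard timing.
    """
    B = np.atleast_2d(np.asarray(beliefs, dtype=float))
    if steps == 1:
        return (B @ spec.returns.T).max(axis=1)
    best = np.full(len(B), -np.inf)
    for a in range(spec.n_actions):
        acc = B @ spec.returns[a]
        pred = B @ spec.transitions[a]
        future = np.zeros(len(B))
        for o in range(spec.n_observations):
            joint = pred * spec.observations[a][:, o]
            lik = joint.sum(axis=1)
            ok = lik > 1e-14
            if ok.any():
                post = np.where(
                    ok[:, None], joint / np.where(ok, lik, 1.0)[:, None], 1.0 / spec.n_states
                )
                vals = exact_pomdp_values(spec, post, steps - 1)
                future[ok] += lik[ok] * vals[ok]
        best = np.maximum(best, acc + spec.discount * future)
    return best
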