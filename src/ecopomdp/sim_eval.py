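"""Generative simulation and Monte-Carlo policy valuation.

Trajectories realize the generative forms of the decision process: states
are drawn from the transition probabilities, observations from the
observation model, and actions come from the policy applied to the current
state (MDP) or to the running belief (POMDP).  All randomness flows from a
single root seed that is split deterministically, so identical seeds give
identical trajectories.

Monte-Carlo valuation is the independent check on the dynamic-programming
solvers: the mean discounted return over many simulated trajectories must
agree with the solver's value function within sampling error.

The module also ships a stylized waterfowl-harvest fixture — a discretized
population POMDP with seasonal survival, recruitment and harvest — as a
*demonstration* model for exercising the toolchain; its parameter values are
illustrative defaults, not estimates for any real population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alpha_solver import AlphaSet, value_at
from .belief_dynamics import update
from .model_core import (
    DecisionProcessSpec,
    StationaryPolicy,
    as_belief,
    EXTENDED,
    INFINITE,
)

__all__ = [
    "Trajectory",
    "sample_trajectory",
    "mc_policy_value",
    "waterfowl_fixture",
    "default_sim_horizon",
]


@dataclass
class Trajectory:
    """A time-indexed record of one simulated management episode."""

    states: list[str]
    actions: list[str]
    returns: list[float]
    observations: list[str] | None
    beliefs: list[np.ndarray] | None
    seed: int
    discount: float

    @property
    def discounted_return(self) -> float:
        return float(
            sum(self.discount ** t * r for t, r in enumerate(self.returns))
        )

    def __len__(self) -> int:
        return len(self.actions)


def default_sim_horizon(spec: DecisionProcessSpec, tail: float = 1e-6) -> int:
    """Horizon at which the discounted tail of an infinite process is
    negligible (relative tail mass below ``tail``)."""
    if spec.horizon != INFINITE:
        return int(spec.horizon)
    if spec.discount >= 1.0:
        raise ValueError("infinite undiscounted horizon needs an explicit cutoff")
    return max(1, int(math.ceil(math.log(tail) / math.log(spec.discount))))


def _sample_index(row: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(row), rng.random(), side="right").clip(0, len(row) - 1))


def _policy_action(policy, spec, state_idx, belief, rng) -> int:
    if policy == "random":
        return int(rng.integers(spec.n_actions))
    if isinstance(policy, StationaryPolicy):
        return spec.action_index(policy.action_of[spec.state_labels[state_idx]])
    if isinstance(policy, AlphaSet):
        if belief is None:
            raise ValueError("alpha-set policy needs a belief (POMDP spec)")
        return value_at(belief, policy)[1]
    if callable(policy):
        a = policy(belief if belief is not None else spec.state_labels[state_idx])
        return a if isinstance(a, (int, np.integer)) else spec.action_index(a)
    raise TypeError(f"unsupported policy type {type(policy).__name__}")


def sample_trajectory(
    spec: DecisionProcessSpec,
    policy,
    start,
    horizon: int | None = None,
    seed: int = 0,
) -> Trajectory:
    """Simulate one episode under ``policy``.

    ``start`` is a state label/index for an observable MDP or an initial
    belief for a POMDP (the true initial state is drawn from it).  The
    policy is a :class:`StationaryPolicy` (MDP), an :class:`AlphaSet`
    (belief-greedy POMDP control), the string ``"random"``, or a callable
    mapping state/belief to an action.
    """
    rng = np.random.default_rng(seed)
    h = default_sim_horizon(spec) if horizon is None else int(horizon)

    if spec.is_pomdp:
        b = as_belief(start, spec.n_states)
        s = _sample_index(b, rng)
    else:
        b = None
        s = start if isinstance(start, (int, np.integer)) else spec.state_index(start)

    states, actions, rewards = [], [], []
    observations: list[str] | None = [] if spec.is_pomdp else None
    beliefs: list[np.ndarray] | None = [] if spec.is_pomdp else None

    for _ in range(h):
        a = _policy_action(policy, spec, s, b, rng)
        states.append(spec.state_labels[s])
        actions.append(spec.action_labels[a])
        rewards.append(float(spec.returns[a, s]))
        if spec.is_pomdp and spec.timing == EXTENDED:
            o = _sample_index(spec.observations[a][s], rng)  # obs from prior state
            P = spec.transition_matrix(a, o) if spec.transitions.ndim == 4 else spec.transitions[a]
            s_next = _sample_index(P[s], rng)
            res = update(b, a, o, spec)
            observations.append(spec.observation_labels[o])
            b = res.posterior.probabilities
            beliefs.append(b.copy())
        elif spec.is_pomdp:
            s_next = _sample_index(spec.transitions[a][s], rng)
            o = _sample_index(spec.observations[a][s_next], rng)
            res = update(b, a, o, spec)
            observations.append(spec.observation_labels[o])
            b = res.posterior.probabilities
            beliefs.append(b.copy())
        else:
            s_next = _sample_index(spec.transitions[a][s], rng)
        s = s_next

    return Trajectory(
        states=states,
        actions=actions,
        returns=rewards,
        observations=observations,
        beliefs=beliefs,
        seed=seed,
        discount=spec.discount,
    )


# ---------------------------------------------------------------------------
# Vectorized Monte-Carlo valuation
# ---------------------------------------------------------------------------

def _vector_sample(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Categorical draw per row of a (n, k) probability matrix."""
    u = rng.random(len(prob_rows))
    return (prob_rows.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(
        0, prob_rows.shape[1] - 1
    )


def _mc_mdp(spec, policy, x0, n, h, rng):
    if policy == "random":
        a_of_state = None
    elif isinstance(policy, StationaryPolicy):
        a_of_state = policy.action_indices(spec)
    else:
        a_of_state = np.array(
            [
                _policy_action(policy, spec, s, None, rng)
                for s in range(spec.n_states)
            ]
        )
    s = np.full(n, x0, dtype=int)
    total = np.zeros(n)
    disc = 1.0
    for _ in range(h):
        a = rng.integers(spec.n_actions, size=n) if a_of_state is None else a_of_state[s]
        total += disc * spec.returns[a, s]
        s = _vector_sample(spec.transitions[a, s], rng)
        disc *= spec.discount
    return total


def _mc_pomdp(spec, policy, b0, n, h, rng):
    if spec.timing == EXTENDED:
        # per-trajectory reference path (extended timing is rare and small)
        seeds = rng.integers(0, 2 ** 31 - 1, size=n)
        return np.array(
            [
                sample_trajectory(spec, policy, b0, horizon=h, seed=int(sd)).discounted_return
                for sd in seeds
            ]
        )
    B = np.tile(as_belief(b0, spec.n_states), (n, 1))
    s = _vector_sample(B, rng)
    total = np.zeros(n)
    disc = 1.0
    if isinstance(policy, AlphaSet):
        mat = policy.matrix
        act_of_vec = policy.actions
    for _ in range(h):
        if policy == "random":
            a = rng.integers(spec.n_actions, size=n)
        elif isinstance(policy, AlphaSet):
            a = act_of_vec[np.argmax(B @ mat.T, axis=1)]
        elif callable(policy):
            a = np.array(
                [_policy_action(policy, spec, s[i], B[i], rng) for i in range(n)]
            )
        else:
            raise TypeError("POMDP simulation needs an AlphaSet, callable or 'random'")
        total += disc * spec.returns[a, s]
        s = _vector_sample(spec.transitions[a, s], rng)
        o = _vector_sample(spec.observations[a, s], rng)
        # grouped Bayes update: B' propto (B @ P_a) * f_a[:, o]
        B_new = np.empty_like(B)
        for ai in np.unique(a):
            m = a == ai
            pred = B[m] @ spec.transitions[ai]
            joint = pred * spec.observations[ai][:, o[m]].T
            B_new[m] = joint / joint.sum(axis=1, keepdims=True)
        B = B_new
        disc *= spec.discount
    return total


def mc_policy_value(
    spec: DecisionProcessSpec,
    policy,
    start,
    n: int = 10_000,
    seed: int = 0,
    horizon: int | None = None,
) -> tuple[float, float]:
    """Mean and standard error of the discounted return over ``n`` replicates.

    Replicates are vectorized over one seeded generator; identical arguments
    give identical estimates.  For infinite-horizon specs the simulation is
    truncated where the discounted tail is negligible (see
    :func:`default_sim_horizon`).
    """
    if n < 2:
        raise ValueError("need at least 2 replicates for a standard error")
    rng = np.random.default_rng(seed)
    h = default_sim_horizon(spec) if horizon is None else int(horizon)
    if spec.is_pomdp:
        totals = _mc_pomdp(spec, policy, start, n, h, rng)
    else:
        x0 = start if isinstance(start, (int, np.integer)) else spec.state_index(start)
        totals = _mc_mdp(spec, policy, x0, n, h, rng)
    return float(totals.mean()), float(totals.std(ddof=1) / np.sqrt(n))


# ---------------------------------------------------------------------------
# Stylized waterfowl-harvest demonstration fixture
# ---------------------------------------------------------------------------

def waterfowl_fixture(
    Ss: float = 0.8,
    Sw: float = 0.9,
    harvest_rates: tuple[float, ...] = (0.1, 0.25, 0.4),
    age_ratio: float = 0.8,
    n_bins: int = 5,
    observation_noise: float = 0.5,
    discount: float = 0.95,
) -> DecisionProcessSpec:
    """A discretized waterfowl-harvest POMDP (demonstration model).

    An annual cycle: spring-summer survival ``Ss`` and recruitment (young
    per adult, ``age_ratio``) grow the spring population, a fall harvest
    removes a rate chosen from ``harvest_rates``, and fall-winter survival
    ``Sw`` carries the remainder to the next spring.  Abundance is tracked
    in ``n_bins`` classes with unit-spaced representative sizes; the
    expected next abundance ``N * Ss * (1 + age_ratio) * (1 - h) * Sw`` is
    mapped to classes by stochastic rounding between its neighbours.
    Monitoring yields a noisy abundance-class estimate: a discretized normal
    around the true class with standard deviation ``observation_noise`` (in
    class units); zero noise reduces the fixture to an observable MDP with an
    identity observation model.  Returns are the expected harvest.
    """
    for r in harvest_rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"harvest rate {r} outside [0, 1]")
    if not (0.0 <= Ss <= 1.0 and 0.0 <= Sw <= 1.0):
        raise ValueError("seasonal survival rates must be in [0, 1]")
    if age_ratio < 0:
        raise ValueError("age ratio must be non-negative")
    if n_bins < 2:
        raise ValueError("need at least 2 abundance classes")

    centers = np.arange(1.0, n_bins + 1.0)  # representative abundances
    na = len(harvest_rates)
    P = np.zeros((na, n_bins, n_bins))
    R = np.zeros((na, n_bins))
    fall_factor = Ss * (1.0 + age_ratio)
    for a, h in enumerate(harvest_rates):
        for i, N in enumerate(centers):
            mu = N * fall_factor * (1.0 - h) * Sw
            c = np.clip(mu - 1.0, 0.0, n_bins - 1.0)  # continuous class coord
            lo = int(np.floor(c))
            frac = c - lo
            P[a, i, lo] += 1.0 - frac
            if frac > 0:
                P[a, i, min(lo + 1, n_bins - 1)] += frac
            R[a, i] = N * fall_factor * h  # expected fall harvest

    obs_labels = tuple(f"est{i + 1}" for i in range(n_bins))
    if observation_noise <= 0:
        F = np.eye(n_bins)
    else:
        idx = np.arange(n_bins)
        F = np.exp(-0.5 * ((idx[None, :] - idx[:, None]) / observation_noise) ** 2)
        F /= F.sum(axis=1, keepdims=True)

    spec = DecisionProcessSpec(
        state_labels=tuple(f"N{i + 1}" for i in range(n_bins)),
        action_labels=tuple(f"h{r:g}" for r in harvest_rates),
        transitions=P,
        returns=R,
        discount=discount,
        horizon=INFINITE,
        observation_labels=obs_labels,
        observations=F,
        name="waterfowl_demo",
    )
    return spec
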