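"""Mixed observability and adaptive management.

Adaptive management of an observed system under structural uncertainty is a
hidden-model MDP (hmMDP): the system state x is monitored exactly, but its
transition law is one of several hypothesised models y, tracked by a model
belief b_y.  Each observed transition (x, a, x') is evidence about the model:

    b'(y)  propto  b(y) * P(x'|x,a,y),

and decisions are made against the belief-weighted mixture dynamics
P(x'|x,a,b_y) = sum_y b(y) P(x'|x,a,y).  Valuation runs dynamic programming
over the product of the state space and a discretized model-belief simplex,
with posterior beliefs projected to the nearest lattice node.

Nonstationary model structure (e.g. climate-driven drift) adds a model
transition matrix P(y'|y): state transitions from x to x' follow model y'
once a model change occurs, and both the prior-model and next-model beliefs
must be tracked.  With an identity model-transition matrix the machinery
reduces exactly to the stationary update.

A general mixed-observability MDP (MOMDP) composes an observable component
with a hidden one into a flat product POMDP in which the observable part of
the state is revealed deterministically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model_core import (
    BeliefState,
    DecisionProcessSpec,
    as_belief,
    INFINITE,
    ROW_TOLERANCE,
)

__all__ = [
    "ModelSet",
    "ModelBelief",
    "mixture_transition",
    "model_belief_update",
    "nonstationary_belief_update",
    "hmmdp_solve",
    "HmmdpSolution",
    "momdp_compose",
    "simplex_lattice",
]

ModelBelief = BeliefState  # a belief over models has the same invariants


@dataclass
class ModelSet:
    """Alternative transition models for an observed system.

    ``transitions[y]`` is the ``(|A|, |X|, |X|)`` transition array of model
    y; ``model_transition``, if present, is the row-stochastic ``P(y'|y)``
    matrix of a nonstationary model structure.  ``returns[y]``, if present,
    gives model-specific returns ``(|A|, |X|)``; otherwise returns come from
    the accompanying spec.
    """

    model_labels: tuple[str, ...]
    transitions: np.ndarray  # (|Y|, |A|, |X|, |X|)
    model_transition: np.ndarray | None = None
    returns: np.ndarray | None = None  # (|Y|, |A|, |X|)

    def __post_init__(self) -> None:
        self.model_labels = tuple(str(y) for y in self.model_labels)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.transitions.ndim != 4 or self.transitions.shape[0] != len(
            self.model_labels
        ):
            raise ValueError("transitions must be (|Y|, |A|, |X|, |X|)")
        rows = self.transitions.reshape(-1, self.transitions.shape[-1])
        if np.any(np.abs(rows.sum(axis=1) - 1.0) > ROW_TOLERANCE) or np.any(rows < 0):
            raise ValueError("per-model transition rows must be stochastic")
        if self.model_transition is not None:
            M = np.asarray(self.model_transition, dtype=float)
            ny = len(self.model_labels)
            if M.shape != (ny, ny):
                raise ValueError("model_transition must be (|Y|, |Y|)")
            if np.any(np.abs(M.sum(axis=1) - 1.0) > ROW_TOLERANCE) or np.any(M < 0):
                raise ValueError("model_transition rows must be stochastic")
            self.model_transition = M
        if self.returns is not None:
            self.returns = np.asarray(self.returns, dtype=float)

    @property
    def n_models(self) -> int:
        return len(self.model_labels)

    @property
    def is_nonstationary(self) -> bool:
        return self.model_transition is not None


def mixture_transition(x: int, a: int, b_y, models: ModelSet) -> np.ndarray:
    """Belief-weighted dynamics P(x'|x,a,b_y) = sum_y b(y) P(x'|x,a,y)."""
    w = as_belief(b_y, models.n_models)
    return w @ models.transitions[:, a, x, :]


def model_belief_update(b_y, x: int, a: int, x_next: int, models: ModelSet) -> BeliefState:
    """Bayes update of the model belief after observing a transition:
    b'(y) = b(y) P(x'|x,a,y) / sum_y b(y) P(x'|x,a,y)."""
    w = as_belief(b_y, models.n_models)
    lik = models.transitions[:, a, x, x_next]
    joint = w * lik
    total = joint.sum()
    if total <= 0.0:
        raise ValueError(
            f"transition {x}->{x_next} under action {a} is impossible in every model"
        )
    return BeliefState(joint / total)


def nonstationary_belief_update(
    b_y, x: int, a: int, x_next: int, models: ModelSet
) -> tuple[BeliefState, BeliefState]:
    """Two-stage update when the model itself drifts via P(y'|y).

    Per prior model y, the predictive probability of the observed transition
    is ``P(x'|x,a,y) = sum_y' P(y'|y) P_{y'}(x'|x,a)`` (the transition is
    governed by the post-change model).  The prior-model posterior is

        b'(y)  propto  b(y) * P(x'|x,a,y),

    and the next-model belief marginalizes each prior model's conditional
    posterior ``b_{y'}(y'|y) propto P(y'|y) P_{y'}(x'|x,a)`` against b'(y).
    Both are returned (prior-model posterior first).  With an identity model
    transition the first component equals :func:`model_belief_update` and the
    second coincides with it.
    """
    if models.model_transition is None:
        raise ValueError("nonstationary update requires a model_transition matrix")
    w = as_belief(b_y, models.n_models)
    M = models.model_transition
    step = models.transitions[:, a, x, x_next]  # P_{y'}(x'|x,a), indexed by y'
    cond_joint = M * step[None, :]              # P(y'|y) P_{y'}(x'|x,a)
    pred = cond_joint.sum(axis=1)               # P(x'|x,a,y)
    total = float(w @ pred)
    if total <= 0.0:
        raise ValueError("observed transition impossible under every model path")
    b_prior = w * pred / total
    with np.errstate(invalid="ignore", divide="ignore"):
        cond_post = np.where(pred[:, None] > 0, cond_joint / pred[:, None], 0.0)
    b_next = b_prior @ cond_post
    return BeliefState(b_prior), BeliefState(b_next)


# ---------------------------------------------------------------------------
# hmMDP dynamic programming over a belief lattice
# ---------------------------------------------------------------------------

def simplex_lattice(n_dims: int, spacing: float) -> np.ndarray:
    """Regular lattice on the probability simplex with the given spacing."""
    k = int(round(1.0 / spacing))
    if k < 1:
        raise ValueError("grid too coarse: spacing must give >= 2 nodes per axis")
    pts = [
        np.array(c, dtype=float) / k
        for c in itertools.product(range(k + 1), repeat=n_dims)
        if sum(c) == k
    ]
    return np.array(pts)


@dataclass
class HmmdpSolution:
    """Values and policy over (state, model-belief node)."""

    grid: np.ndarray                 # (n_nodes, |Y|)
    values: np.ndarray               # (|X|, n_nodes)
    actions: np.ndarray              # (|X|, n_nodes) action indices
    spec: DecisionProcessSpec
    models: ModelSet

    def value_at(self, x: int, b_y) -> float:
        node = int(np.argmin(np.abs(self.grid - as_belief(b_y)).sum(axis=1)))
        return float(self.values[x, node])

    def action_at(self, x: int, b_y) -> str:
        node = int(np.argmin(np.abs(self.grid - as_belief(b_y)).sum(axis=1)))
        return self.spec.action_labels[self.actions[x, node]]


def hmmdp_solve(
    spec: DecisionProcessSpec,
    models: ModelSet,
    grid_resolution: float = 0.05,
    horizon: int | str | None = None,
    epsilon: float = 1e-8,
    max_iterations: int = 10 ** 5,
) -> HmmdpSolution:
    """Dynamic programming for an observed MDP with a hidden model.

    The model-belief simplex is discretized on a regular lattice; at each
    (state, node, action) the expected value mixes over models and successor
    states, the posterior model belief after each imagined transition being
    projected to the nearest lattice node.  Finite horizons run backward
    induction; infinite horizons iterate to a ``epsilon`` sup-norm fixed
    point (discount < 1 required).  The discount multiplies the future term.
    """
    if models.is_nonstationary:
        raise ValueError(
            "hmmdp_solve assumes stationary models; nonstationary structures "
            "need the two-stage belief (see nonstationary_belief_update)"
        )
    grid = simplex_lattice(models.n_models, grid_resolution)
    nx, na, ng = spec.n_states, spec.n_actions, len(grid)

    if models.returns is not None:
        # model-averaged immediate return per node: R(a|x,b) = sum_y b R(a|x,y)
        Rnode = np.einsum("gy,yax->axg", grid, models.returns)
    else:
        Rnode = np.repeat(spec.returns[:, :, None], ng, axis=2)

    # mixture transitions per node and nearest-node successor beliefs
    mix = np.einsum("gy,yaxj->axgj", grid, models.transitions)  # P(x'|x,a,b_g)
    succ = np.empty((na, nx, ng, nx), dtype=int)
    for a in range(na):
        for x in range(nx):
            for g in range(ng):
                for xn in range(nx):
                    lik = models.transitions[:, a, x, xn]
                    joint = grid[g] * lik
                    tot = joint.sum()
                    post = joint / tot if tot > 0 else grid[g]
                    succ[a, x, g, xn] = int(
                        np.argmin(((grid - post) ** 2).sum(axis=1))
                    )

    h = spec.horizon if horizon is None else horizon

    def sweep(v_next: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # v_next: (|X|, n_nodes)
        future = np.empty((na, nx, ng))
        xn_idx = np.arange(nx)
        for a in range(na):
            for x in range(nx):
                # element [g, xn] = V_next(xn, node nearest the posterior belief)
                vn = v_next[xn_idx[None, :], succ[a, x]]  # (ng, nx)
                future[a, x] = (mix[a, x] * vn).sum(axis=1)
        Q = Rnode + spec.discount * future  # (A, X, G)
        acts = np.argmax(Q, axis=0)
        vals = np.take_along_axis(Q, acts[None], axis=0)[0]
        return vals, acts

    if h != INFINITE:
        v = np.zeros((nx, ng))
        acts = np.zeros((nx, ng), dtype=int)
        for k in range(int(h)):
            if k == 0:
                Q = Rnode
                acts = np.argmax(Q, axis=0)
                v = np.take_along_axis(Q, acts[None], axis=0)[0]
            else:
                v, acts = sweep(v)
        return HmmdpSolution(grid, v, acts, spec, models)

    if spec.discount >= 1.0:
        raise ValueError("infinite horizon requires discount < 1")
    v = np.zeros((nx, ng))
    for _ in range(max_iterations):
        v_new, acts = sweep(v)
        if np.max(np.abs(v_new - v)) < epsilon:
            return HmmdpSolution(grid, v_new, acts, spec, models)
        v = v_new
    raise RuntimeError("hmMDP value iteration did not converge")


# ---------------------------------------------------------------------------
# MOMDP composition
# ---------------------------------------------------------------------------

def momdp_compose(
    observable_spec: DecisionProcessSpec | None,
    hidden_spec: DecisionProcessSpec | None,
) -> DecisionProcessSpec:
    """Compose an observable MDP and a hidden POMDP into a flat product POMDP.

    The product state is (x, y) with independent component dynamics
    ``P(x'|x,a) P(y'|y,a)``; the observation is the pair (x', o_y) where the
    x-component is revealed deterministically and o_y follows the hidden
    component's observation model.  Returns add across components.  With no
    hidden component the observable MDP is returned unchanged; with no
    observable component, the hidden POMDP.
    """
    if hidden_spec is None:
        if observable_spec is None:
            raise ValueError("both components empty")
        return observable_spec
    if observable_spec is None:
        return hidden_spec
    if observable_spec.action_labels != hidden_spec.action_labels:
        raise ValueError(
            f"incompatible action sets: {observable_spec.action_labels} "
            f"vs {hidden_spec.action_labels}"
        )
    if not hidden_spec.is_pomdp:
        raise ValueError("hidden component must carry an observation model")
    nx, ny = observable_spec.n_states, hidden_spec.n_states
    na = observable_spec.n_actions
    noy = hidden_spec.n_observations

    states = tuple(
        f"{sx}|{sy}"
        for sx in observable_spec.state_labels
        for sy in hidden_spec.state_labels
    )
    obs = tuple(
        f"{sx}|{oy}"
        for sx in observable_spec.state_labels
        for oy in hidden_spec.observation_labels
    )
    P = np.einsum(
        "aij,akl->aikjl", observable_spec.transitions, hidden_spec.transitions
    ).reshape(na, nx * ny, nx * ny)
    # f((ox,oy)|(x',y'),a) = 1[ox=x'] f(oy|y',a)
    F = np.zeros((na, nx * ny, nx * noy))
    for a in range(na):
        for ix in range(nx):
            for iy in range(ny):
                F[a, ix * ny + iy, ix * noy : (ix + 1) * noy] = hidden_spec.observations[
                    a, iy
                ]
    R = (
        observable_spec.returns[:, :, None] + hidden_spec.returns[:, None, :]
    ).reshape(na, nx * ny)
    return DecisionProcessSpec(
        state_labels=states,
        action_labels=observable_spec.action_labels,
        transitions=P,
        returns=R,
        discount=observable_spec.discount,
        horizon=observable_spec.horizon,
        observation_labels=obs,
        observations=F,
        name="momdp_product",
    )
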