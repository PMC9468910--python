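"""Dynamic programming for fully observable MDPs.

Finite horizons are solved by backward induction on the Bellman equation

    V_t(x) = max_a [ R(a|x) + lambda * sum_x' P(x'|x,a) V_{t+1}(x') ],

starting from V_T(x) = max_a R(a|x).  Infinite discounted horizons are
solved by policy iteration: closed-form evaluation of a stationary policy
pi via the linear system (I - lambda * P_pi) V = R_pi, alternated with
greedy improvement until the policy repeats.

Ties among maximizing actions are always broken toward the lowest action
index so that returned policies are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .model_core import DecisionProcessSpec, StationaryPolicy, INFINITE

__all__ = [
    "ValueTable",
    "bellman_action_values",
    "backward_induction",
    "evaluate_stationary_policy",
    "policy_iteration",
]


@dataclass
class ValueTable:
    """Epoch-indexed optimal (or policy) values and actions.

    ``values`` has shape ``(n_epochs, |X|)`` for finite horizons or
    ``(1, |X|)`` for stationary solutions; ``epoch_labels`` names the rows
    (``"T"``, ``"T-1"``, ... or ``"stationary"``).  ``q_values`` holds the
    per-action candidate values ``(n_epochs, |A|, |X|)`` from which the
    maxima were taken.
    """

    values: np.ndarray
    actions: np.ndarray  # action indices, same shape as values
    epoch_labels: tuple[str, ...]
    spec: DecisionProcessSpec
    q_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.actions = np.atleast_2d(np.asarray(self.actions, dtype=int))
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite value entries")
        if self.values.shape != self.actions.shape:
            raise ValueError("values/actions shape mismatch")

    def value(self, epoch: str, state: str) -> float:
        return float(
            self.values[self.epoch_labels.index(epoch), self.spec.state_index(state)]
        )

    def action(self, epoch: str, state: str) -> str:
        a = self.actions[self.epoch_labels.index(epoch), self.spec.state_index(state)]
        return self.spec.action_labels[a]

    def action_value(self, epoch: str, action: str, state: str) -> float:
        """Candidate (not necessarily optimal) value of ``action`` at (epoch, state)."""
        if self.q_values is None:
            raise ValueError("no per-action values recorded")
        return float(
            self.q_values[
                self.epoch_labels.index(epoch),
                self.spec.action_index(action),
                self.spec.state_index(state),
            ]
        )

    def stationary_policy(self) -> StationaryPolicy:
        return StationaryPolicy.from_indices(self.actions[0], self.spec)

    def as_frame(self) -> pd.DataFrame:
        """Tidy (epoch, state, action, value) table."""
        rows = [
            {
                "epoch": ep,
                "state": s,
                "action": self.spec.action_labels[self.actions[i, j]],
                "value": self.values[i, j],
            }
            for i, ep in enumerate(self.epoch_labels)
            for j, s in enumerate(self.spec.state_labels)
        ]
        return pd.DataFrame(rows)


def bellman_action_values(
    spec: DecisionProcessSpec, v_next: np.ndarray | None
) -> np.ndarray:
    """Per-action candidate values ``Q(a, x) = R(a|x) + lambda * P_a v_next``.

    With ``v_next`` ``None`` (terminal epoch) the future term is zero.
    """
    Q = spec.returns.copy()
    if v_next is not None:
        Q = Q + spec.discount * spec.transitions @ np.asarray(v_next, dtype=float)
    return Q


def backward_induction(
    spec: DecisionProcessSpec, horizon: int | None = None
) -> ValueTable:
    """Solve a finite-horizon observable MDP by backward induction.

    ``horizon`` (defaulting to ``spec.horizon``) counts decision epochs: the
    terminal epoch T plus ``horizon - 1`` earlier epochs.  Rows of the result
    run from epoch ``T`` down to ``T-(horizon-1)``.
    """
    if spec.is_pomdp:
        raise ValueError("spec has observations; use the alpha-vector solver")
    h = spec.horizon if horizon is None else horizon
    if h == INFINITE:
        raise ValueError("infinite horizon: use policy_iteration instead")
    h = int(h)
    if h < 1:
        raise ValueError("horizon must be >= 1")

    values = np.empty((h, spec.n_states))
    actions = np.empty((h, spec.n_states), dtype=int)
    qvals = np.empty((h, spec.n_actions, spec.n_states))
    v_next = None
    for k in range(h):  # k = epochs before terminal
        Q = bellman_action_values(spec, v_next)
        qvals[k] = Q
        actions[k] = np.argmax(Q, axis=0)  # argmax returns lowest index on ties
        values[k] = Q[actions[k], np.arange(spec.n_states)]
        v_next = values[k]
    labels = tuple("T" if k == 0 else f"T-{k}" for k in range(h))
    return ValueTable(values, actions, labels, spec, q_values=qvals)


def evaluate_stationary_policy(
    spec: DecisionProcessSpec, policy: StationaryPolicy
) -> ValueTable:
    """Closed-form value of a stationary policy over an infinite horizon.

    Solves ``(I - lambda * P_pi) V = R_pi`` where ``P_pi`` and ``R_pi`` are
    the transition matrix and return vector induced by the policy.
    """
    if spec.is_pomdp:
        raise ValueError("spec has observations; stationary evaluation is for MDPs")
    a_idx = policy.action_indices(spec)
    s_idx = np.arange(spec.n_states)
    P_pi = spec.transitions[a_idx, s_idx]
    R_pi = spec.returns[a_idx, s_idx]
    A = np.eye(spec.n_states) - spec.discount * P_pi
    if spec.discount >= 1.0 and abs(np.linalg.det(A)) < 1e-12:
        raise np.linalg.LinAlgError(
            "undiscounted recurrent chain: value series does not converge"
        )
    V = scipy.linalg.solve(A, R_pi)
    resid = np.max(np.abs(V - (R_pi + spec.discount * P_pi @ V)))
    if resid > 1e-8:
        raise np.linalg.LinAlgError(f"policy evaluation residual {resid:.3g}")
    return ValueTable(
        V[None, :], a_idx[None, :], ("stationary",), spec, q_values=None
    )


def policy_iteration(
    spec: DecisionProcessSpec,
) -> tuple[StationaryPolicy, ValueTable]:
    """Optimal stationary policy and values for a discounted infinite horizon.

    Starts from the myopic policy ``argmax_a R(a|x)`` and alternates exact
    policy evaluation with greedy improvement until the policy repeats.  The
    returned values satisfy the Bellman optimality equation to 1e-8.
    """
    if spec.is_pomdp:
        raise ValueError("spec has observations; use the alpha-vector solver")
    if spec.discount >= 1.0:
        raise ValueError("policy iteration requires discount < 1")
    a_idx = np.argmax(spec.returns, axis=0)
    s_idx = np.arange(spec.n_states)
    max_sweeps = spec.n_actions ** spec.n_states + 1
    table = None
    for _ in range(max_sweeps):
        policy = StationaryPolicy.from_indices(a_idx, spec)
        table = evaluate_stationary_policy(spec, policy)
        Q = bellman_action_values(spec, table.values[0])
        improved = np.argmax(Q, axis=0)
        # keep the incumbent action unless a strict improvement exists, so
        # the loop terminates on value ties
        keep = Q[improved, s_idx] <= Q[a_idx, s_idx] + 1e-12
        improved[keep] = a_idx[keep]
        if np.array_equal(improved, a_idx):
            V = table.values[0]
            bellman = np.max(Q, axis=0)
            if np.max(np.abs(V - bellman)) > 1e-8:
                raise RuntimeError("policy iteration converged to a non-optimal fixed point")
            table.q_values = Q[None, :, :]
            return policy, table
        a_idx = improved
    raise RuntimeError("policy iteration failed to converge (internal error)")
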