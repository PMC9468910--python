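"""Belief prediction and Bayesian updating for POMDPs.

Under standard timing (observation after the transition) the belief over the
next state x' given action a and observation o' is

    b_{a,o'}(x') = f(o'|x',a) P(x'|b,a) / P(o'|b,a),

with predictive P(x'|b,a) = sum_x b(x) P(x'|x,a) and normalizer
P(o'|b,a) = sum_x' f(o'|x',a) P(x'|b,a).

Under extended timing (observation before the transition) the observation o
is tied to the prior state and may condition the transition:

    b_{a,o}(x') = sum_x f(o|x,a) P(x'|x,a,o) b(x) / f(o|b,a),

with f(o|b,a) = sum_x f(o|x,a) b(x).

Zero-probability observations raise rather than silently renormalizing 0/0:
an impossible observation indicates a model error, not a degenerate belief.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import BeliefState, DecisionProcessSpec, as_belief, EXTENDED, STANDARD

__all__ = [
    "BeliefUpdateResult",
    "ImpossibleObservationError",
    "predict",
    "observation_likelihood",
    "update_standard",
    "update_extended",
    "update",
]


class ImpossibleObservationError(ValueError):
    """The observation has probability zero under the current belief."""


@dataclass
class BeliefUpdateResult:
    posterior: BeliefState
    observation_probability: float


def _action(spec: DecisionProcessSpec, a) -> int:
    return a if isinstance(a, (int, np.integer)) else spec.action_index(a)


def _obs(spec: DecisionProcessSpec, o) -> int:
    return o if isinstance(o, (int, np.integer)) else spec.observation_index(o)


def predict(b, a, spec: DecisionProcessSpec) -> BeliefState:
    """Predictive state distribution P(x'|b,a) = sum_x b(x) P(x'|x,a)."""
    p = as_belief(b, spec.n_states)
    ai = _action(spec, a)
    if spec.transitions.ndim == 4:
        raise ValueError(
            "observation-conditioned transitions: use update_extended, which "
            "predicts per observation"
        )
    return BeliefState(p @ spec.transitions[ai])


def observation_likelihood(b, a, o, spec: DecisionProcessSpec) -> float:
    """P(o'|b,a) under standard timing.

    For an extended-timing spec the prior-observation likelihood is
    ``f(o|b,a) = sum_x f(o|x,a) b(x)``; call with such a spec raises and
    names that form.
    """
    if spec.timing == EXTENDED:
        raise ValueError(
            "extended timing: the observation precedes the transition; its "
            "likelihood is f(o|b,a) = sum_x f(o|x,a) b(x) (see update_extended)"
        )
    p = as_belief(b, spec.n_states)
    ai, oi = _action(spec, a), _obs(spec, o)
    pred = p @ spec.transitions[ai]
    return float(pred @ spec.observations[ai][:, oi])


def update_standard(b, a, o, spec: DecisionProcessSpec) -> BeliefUpdateResult:
    """Posterior belief after acting and then observing (standard timing)."""
    if spec.timing != STANDARD:
        raise ValueError("spec timing is not standard")
    p = as_belief(b, spec.n_states)
    ai, oi = _action(spec, a), _obs(spec, o)
    joint = (p @ spec.transitions[ai]) * spec.observations[ai][:, oi]
    lik = float(joint.sum())
    if lik <= 0.0:
        raise ImpossibleObservationError(
            f"observation {spec.observation_labels[oi]!r} has probability 0 "
            f"under belief {p} and action {spec.action_labels[ai]!r}"
        )
    return BeliefUpdateResult(BeliefState(joint / lik), lik)


def update_extended(b, a, o, spec: DecisionProcessSpec) -> BeliefUpdateResult:
    """Posterior belief when the observation precedes the transition.

    The transition array may be observation-conditioned ``P(x'|x,a,o)``
    (4-d); a plain ``P(x'|x,a)`` array is used for every observation, since
    extended timing merely *allows* observation dependence.
    """
    if spec.timing != EXTENDED:
        raise ValueError("spec timing is not extended")
    p = as_belief(b, spec.n_states)
    ai, oi = _action(spec, a), _obs(spec, o)
    f_prior = spec.observations[ai][:, oi]  # f(o|x,a), prior-state indexed
    lik = float(f_prior @ p)
    if lik <= 0.0:
        raise ImpossibleObservationError(
            f"observation {spec.observation_labels[oi]!r} has prior "
            f"probability 0 under belief {p}"
        )
    P = spec.transition_matrix(ai, oi) if spec.transitions.ndim == 4 else spec.transitions[ai]
    posterior = (p * f_prior) @ P / lik
    return BeliefUpdateResult(BeliefState(posterior), lik)


def update(b, a, o, spec: DecisionProcessSpec) -> BeliefUpdateResult:
    """Timing-dispatching belief update."""
    if spec.timing == EXTENDED:
        return update_extended(b, a, o, spec)
    return update_standard(b, a, o, spec)
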