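"""Core domain types for discrete Markov decision processes in ecology.

A managed ecological system is modelled as a finite Markov decision process
(MDP) or partially observable MDP (POMDP): a set of system states ``X`` (e.g.
abundance classes of a nuisance species), actions ``A`` available to a
manager, per-action Markov transition probabilities ``P(x'|x,a)``, immediate
returns ``R(a|x)`` in arbitrary management units, a discount factor
``lambda`` and a (possibly infinite) time horizon.  A POMDP additionally
carries a finite observation set ``O`` and an observation model
``f(o'|x',a)`` linking what a monitoring programme records to the true,
unobserved state.

Two observation timings are supported.  Under *standard* timing the
observation is generated after the state transition (``x, a -> x' -> o'``)
and cannot influence it.  Under *extended* timing the observation precedes
the transition (``x, a -> o -> x'``) and the transition probabilities may be
conditioned on it, ``P(x'|x,a,o)``.

All arrays are dense NumPy arrays ordered like the label tuples; labels are
the external interface and indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, InitVar
from typing import Sequence

import numpy as np

__all__ = [
    "SpecValidationError",
    "DecisionProcessSpec",
    "BeliefState",
    "PolicyTree",
    "StationaryPolicy",
    "as_belief",
    "validate_spec",
    "builtin_example",
    "BackcastFixture",
    "STANDARD",
    "EXTENDED",
]

#: per-row absolute tolerance for stochasticity; rows within it are
#: renormalized silently, beyond it rejected (absorbs decimal rounding
#: like 0.3/0.7 literals)
ROW_TOLERANCE = 1e-9

STANDARD = "standard"
EXTENDED = "extended"
INFINITE = "infinite"


class SpecValidationError(ValueError):
    """Raised when a decision-process specification violates an invariant."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(self.diagnostics))


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    out: list[str] = []
    if len(labels) == 0:
        out.append(f"{what}: label list is empty")
    if len(set(labels)) != len(labels):
        out.append(f"{what}: duplicate labels in {list(labels)}")
    return out


def _check_rows(arr: np.ndarray, what: str) -> list[str]:
    """Diagnostics for a stacked array whose last axis must be stochastic."""
    out: list[str] = []
    rows = arr.reshape(-1, arr.shape[-1])
    for i, row in enumerate(rows):
        idx = tuple(int(k) for k in np.unravel_index(i * arr.shape[-1], arr.shape)[:-1])
        if (row < -ROW_TOLERANCE).any():
            out.append(f"{what}{list(idx)}: negative entry {row.min():.6g}")
        s = row.sum()
        if abs(s - 1.0) > ROW_TOLERANCE:
            out.append(f"{what}{list(idx)}: row sums to {s:.6g}")
    return out


def _renormalize(arr: np.ndarray) -> np.ndarray:
    """Renormalize rows already within ROW_TOLERANCE of stochastic."""
    s = arr.sum(axis=-1, keepdims=True)
    ok = np.abs(s - 1.0) <= ROW_TOLERANCE
    return np.where(ok & (s > 0), arr / np.where(s > 0, s, 1.0), arr)


@dataclass(eq=False)
class DecisionProcessSpec:
    """A finite (PO)MDP: states, actions, dynamics, returns, horizon.

    Parameters
    ----------
    state_labels, action_labels, observation_labels
        Ordered, duplicate-free identifiers.  ``observation_labels`` is
        ``None`` for a fully observable MDP.
    transitions
        ``(|A|, |X|, |X|)`` array of ``P(x'|x,a)``; rows (last axis) are
        stochastic.  With ``timing="extended"`` an observation-conditioned
        array ``(|A|, |O|, |X|, |X|)`` of ``P(x'|x,a,o)`` may be given
        instead; a 3-d array is then taken as observation-independent.
    observations
        ``(|A|, |X|, |O|)`` array of ``f(o'|x',a)`` (standard timing, the
        state index is the *posterior* state) or ``f(o|x,a)`` (extended
        timing, the state index is the *prior* state).  A 2-d ``(|X|, |O|)``
        array is broadcast as action-independent, the common case where
        monitoring does not depend on the management action.
    returns
        ``(|A|, |X|)`` real array of ``R(a|x)``; negative entries are
        admissible (costs).  A transition-based ``(|A|, |X|, |X|)`` array
        ``R(a|x,x')`` is collapsed on construction via
        ``R(a|x) = sum_x' P(x'|x,a) R(a|x,x')``.
    discount
        lambda in (0, 1].
    horizon
        A positive integer number of decision epochs, or ``"infinite"``.
    timing
        ``"standard"`` or ``"extended"``; meaningful only with observations.
    """

    state_labels: tuple[str, ...]
    action_labels: tuple[str, ...]
    transitions: np.ndarray
    returns: np.ndarray
    discount: float = 1.0
    horizon: int | str = INFINITE
    observation_labels: tuple[str, ...] | None = None
    observations: np.ndarray | None = None
    timing: str = STANDARD
    name: str = ""
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.state_labels = tuple(str(s) for s in self.state_labels)
        self.action_labels = tuple(str(a) for a in self.action_labels)
        if self.observation_labels is not None:
            self.observation_labels = tuple(str(o) for o in self.observation_labels)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.returns = np.asarray(self.returns, dtype=float)
        if self.observations is not None:
            obs = np.asarray(self.observations, dtype=float)
            if obs.ndim == 2:  # action-independent f(o|x)
                obs = np.broadcast_to(obs, (len(self.action_labels),) + obs.shape).copy()
            self.observations = obs
        if self.returns.ndim == 3:  # transition-based returns, collapse
            P = self.transitions
            if P.ndim != 3:
                raise SpecValidationError(
                    ["transition-based returns require P(x'|x,a) transitions"]
                )
            self.returns = (P * self.returns).sum(axis=-1)
        if validate:
            diags = validate_spec(self)
            if diags:
                raise SpecValidationError(diags)
            # rows within ROW_TOLERANCE of 1 produce no diagnostic; make
            # them exactly stochastic so downstream algebra is clean
            self.transitions = _renormalize(self.transitions)
            if self.observations is not None:
                self.observations = _renormalize(self.observations)

    # ---- sizes -----------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_actions(self) -> int:
        return len(self.action_labels)

    @property
    def n_observations(self) -> int:
        return 0 if self.observation_labels is None else len(self.observation_labels)

    @property
    def is_pomdp(self) -> bool:
        return self.observation_labels is not None

    @property
    def is_infinite_horizon(self) -> bool:
        return self.horizon == INFINITE

    # ---- lookups ---------------------------------------------------------
    def state_index(self, label: str) -> int:
        return self.state_labels.index(str(label))

    def action_index(self, label: str) -> int:
        return self.action_labels.index(str(label))

    def observation_index(self, label: str) -> int:
        if self.observation_labels is None:
            raise ValueError("spec has no observations")
        return self.observation_labels.index(str(label))

    def transition_matrix(self, a: int, o: int | None = None) -> np.ndarray:
        """``P(x'|x,a)`` or, for extended o-conditioned dynamics, ``P(x'|x,a,o)``."""
        if self.transitions.ndim == 4:
            if o is None:
                raise ValueError("observation-conditioned transitions need o")
            return self.transitions[a, o]
        return self.transitions[a]

    def observation_matrix(self, a: int) -> np.ndarray:
        if self.observations is None:
            raise ValueError("spec has no observation model")
        return self.observations[a]

    def replace(self, **changes) -> "DecisionProcessSpec":
        """A copy with the given fields replaced (re-validated)."""
        kw = dict(
            state_labels=self.state_labels,
            action_labels=self.action_labels,
            transitions=self.transitions,
            returns=self.returns,
            discount=self.discount,
            horizon=self.horizon,
            observation_labels=self.observation_labels,
            observations=self.observations,
            timing=self.timing,
            name=self.name,
        )
        kw.update(changes)
        return DecisionProcessSpec(**kw)

    def equals(self, other: "DecisionProcessSpec", atol: float = 1e-12) -> bool:
        if (
            self.state_labels != other.state_labels
            or self.action_labels != other.action_labels
            or self.observation_labels != other.observation_labels
            or self.timing != other.timing
            or self.horizon != other.horizon
            or abs(self.discount - other.discount) > atol
        ):
            return False
        if not np.allclose(self.transitions, other.transitions, atol=atol, rtol=0):
            return False
        if not np.allclose(self.returns, other.returns, atol=atol, rtol=0):
            return False
        if (self.observations is None) != (other.observations is None):
            return False
        if self.observations is not None and not np.allclose(
            self.observations, other.observations, atol=atol, rtol=0
        ):
            return False
        return True


def validate_spec(spec: DecisionProcessSpec) -> list[str]:
    """Return diagnostics (empty iff all invariants hold); never raises.

    Each diagnostic names the offending field, index and observed value.
    Returns are unconstrained reals (costs may be negative) and generate no
    diagnostics.
    """
    diags: list[str] = []
    diags += _check_labels(spec.state_labels, "state_labels")
    diags += _check_labels(spec.action_labels, "action_labels")
    nx, na = len(spec.state_labels), len(spec.action_labels)

    P = np.asarray(spec.transitions, dtype=float)
    if P.ndim == 3:
        if P.shape != (na, nx, nx):
            diags.append(f"transitions: shape {P.shape} != {(na, nx, nx)}")
        else:
            diags += _check_rows(P, "transitions")
    elif P.ndim == 4:
        if spec.timing != EXTENDED:
            diags.append("transitions: P(x'|x,a,o) arrays require timing=extended")
        no = 0 if spec.observation_labels is None else len(spec.observation_labels)
        if P.shape != (na, no, nx, nx):
            diags.append(f"transitions: shape {P.shape} != {(na, no, nx, nx)}")
        else:
            diags += _check_rows(P, "transitions")
    else:
        diags.append(f"transitions: expected 3-d or 4-d array, got {P.ndim}-d")

    R = np.asarray(spec.returns, dtype=float)
    if R.shape != (na, nx):
        diags.append(f"returns: shape {R.shape} != {(na, nx)}")
    elif not np.isfinite(R).all():
        diags.append("returns: non-finite entry")

    if spec.observation_labels is not None:
        diags += _check_labels(spec.observation_labels, "observation_labels")
        no = len(spec.observation_labels)
        if spec.observations is None:
            diags.append("observations: POMDP spec missing observation probabilities")
        else:
            f = np.asarray(spec.observations, dtype=float)
            if f.shape != (na, nx, no):
                diags.append(f"observations: shape {f.shape} != {(na, nx, no)}")
            else:
                diags += _check_rows(f, "observations")
    elif spec.observations is not None:
        diags.append("observations: probabilities given but no observation labels")

    if not (0.0 < spec.discount <= 1.0):
        diags.append(f"discount: {spec.discount} outside (0, 1]")
    if spec.horizon != INFINITE and (
        not isinstance(spec.horizon, (int, np.integer)) or spec.horizon < 1
    ):
        diags.append(f"horizon: {spec.horizon!r} is neither a positive integer nor 'infinite'")
    if spec.timing not in (STANDARD, EXTENDED):
        diags.append(f"timing: {spec.timing!r} not in {{standard, extended}}")
    return diags


# ---------------------------------------------------------------------------
# Belief states
# ---------------------------------------------------------------------------

@dataclass
class BeliefState:
    """A probability vector over system states (or models) — the decision
    variable under partial observability."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1:
            raise ValueError("belief must be a 1-d probability vector")
        if (p < -ROW_TOLERANCE).any():
            raise ValueError(f"belief has negative entry: {p}")
        s = p.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"belief sums to {s:.6g}, not 1")
        self.probabilities = np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()

    @classmethod
    def uniform(cls, n: int) -> "BeliefState":
        return cls(np.full(n, 1.0 / n))

    @classmethod
    def degenerate(cls, i: int, n: int) -> "BeliefState":
        p = np.zeros(n)
        p[i] = 1.0
        return cls(p)

    def entropy(self) -> float:
        p = self.probabilities[self.probabilities > 0]
        return float(-(p * np.log(p)).sum())

    def __len__(self) -> int:
        return len(self.probabilities)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probabilities, dtype=dtype)


def as_belief(b, n: int | None = None) -> np.ndarray:
    """Coerce a BeliefState or array-like to a validated probability vector."""
    if isinstance(b, BeliefState):
        p = b.probabilities
    else:
        p = BeliefState(np.asarray(b, dtype=float)).probabilities
    if n is not None and len(p) != n:
        raise ValueError(f"belief length {len(p)} != {n}")
    return p


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------

@dataclass
class PolicyTree:
    """A conditional plan: a root action, then one subtree per observation
    (POMDP) or per state (MDP), down to a fixed depth."""

    root_action: str
    branches: dict[str, "PolicyTree"] = field(default_factory=dict)
    depth: int = 1

    def check(self, branch_keys: Sequence[str]) -> None:
        """Raise unless branch keys exactly cover the key set at every level
        and all leaves sit at equal depth."""
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.depth == 1:
            if self.branches:
                raise ValueError("leaf node has branches")
            return
        if set(self.branches) != set(branch_keys):
            raise ValueError(
                f"branches {sorted(self.branches)} != expected {sorted(branch_keys)}"
            )
        for sub in self.branches.values():
            if sub.depth != self.depth - 1:
                raise ValueError("unequal leaf depths")
            sub.check(branch_keys)


@dataclass
class StationaryPolicy:
    """A time-invariant state -> action map for an observable MDP."""

    action_of: dict[str, str]

    def check(self, spec: DecisionProcessSpec) -> None:
        missing = set(spec.state_labels) - set(self.action_of)
        if missing:
            raise ValueError(f"policy undefined for states {sorted(missing)}")
        bad = set(self.action_of.values()) - set(spec.action_labels)
        if bad:
            raise ValueError(f"policy uses unknown actions {sorted(bad)}")

    def action_indices(self, spec: DecisionProcessSpec) -> np.ndarray:
        self.check(spec)
        return np.array(
            [spec.action_index(self.action_of[s]) for s in spec.state_labels], dtype=int
        )

    @classmethod
    def from_indices(cls, idx: Sequence[int], spec: DecisionProcessSpec) -> "StationaryPolicy":
        return cls({s: spec.action_labels[a] for s, a in zip(spec.state_labels, idx)})


# ---------------------------------------------------------------------------
# Built-in fixtures: nuisance-species control examples
# ---------------------------------------------------------------------------

# Two abundance states (x1 low, x2 high); actions a1 "no investment",
# a2 "habitat alteration", a3 "trap and remove".  Returns mix action costs
# and the social value of low abundance.
_NUISANCE_P = np.array(
    [
        [[0.3, 0.7], [0.0, 1.0]],  # a1: unmanaged, high abundance absorbing
        [[0.8, 0.2], [0.3, 0.7]],  # a2: habitat alteration
        [[0.6, 0.4], [0.8, 0.2]],  # a3: trapping, best at reducing high abundance
    ]
)
_NUISANCE_R = np.array(
    [
        [14.5, 5.0],  # a1
        [12.0, 7.5],  # a2
        [10.0, 5.5],  # a3
    ]
)
# Monitoring yields a low/medium/high count o1..o3 stochastically tied to the
# true abundance class; action-independent.
_NUISANCE_F = np.array(
    [
        [0.1, 0.6, 0.3],  # x1
        [0.5, 0.4, 0.1],  # x2
    ]
)


@dataclass
class BackcastFixture:
    """Two-action, two-state stage-valuation fixture.

    ``returns`` holds R(a|x) for actions a1, a2; ``lines`` maps each triple
    (prior action, next action, observation) to an ``(intercept, slope)``
    pair describing a backcast next-stage value that is linear in the belief
    b = Pr(x1).  ``discount`` is the stage discount factor.
    """

    returns: np.ndarray
    lines: dict[tuple[str, str, str], tuple[float, float]]
    discount: float = 0.9
    action_labels: tuple[str, ...] = ("a1", "a2")
    observation_labels: tuple[str, ...] = ("o1", "o2", "o3")


_BACKCAST_RETURNS = np.array([[2.3, 7.9], [8.1, 2.5]])
_BACKCAST_LINES = {
    ("a1", "a1", "o1"): (2.8, 5.2),
    ("a1", "a1", "o2"): (7.9, -6.8),
    ("a1", "a1", "o3"): (7.5, -3.4),
    ("a1", "a2", "o1"): (4.8, -3.1),
    ("a1", "a2", "o2"): (0.2, 6.4),
    ("a1", "a2", "o3"): (2.5, 2.1),
    ("a2", "a1", "o1"): (4.3, 3.8),
    ("a2", "a1", "o2"): (0.3, 7.7),
    ("a2", "a1", "o3"): (6.2, -2.4),
    ("a2", "a2", "o1"): (6.2, -2.3),
    ("a2", "a2", "o2"): (7.9, -2.4),
    ("a2", "a2", "o3"): (3.9, 2.1),
}

_EXAMPLE_NAMES = (
    "nuisance_mdp",
    "nuisance_obs_pomdp",
    "two_action_backcast_fixture",
    "waterfowl_demo",
)


def builtin_example(name: str):
    """Return a built-in example model by name.

    ``nuisance_mdp``
        2-state, 3-action observable MDP for nuisance-species control,
        discount 0.9, infinite horizon.
    ``nuisance_obs_pomdp``
        The same system with a 3-level monitoring observation model.
        The discount 0.9 is a documented modelling assumption (override via
        ``spec.replace(discount=...)``).
    ``two_action_backcast_fixture``
        A :class:`BackcastFixture` with two actions' return vectors and the
        twelve per-(action, action, observation) backcast value lines for
        one stage of POMDP valuation.
    ``waterfowl_demo``
        A stylized discretized waterfowl-harvest POMDP (see
        :func:`ecopomdp.sim_eval.waterfowl_fixture`).
    """
    if name == "nuisance_mdp":
        return DecisionProcessSpec(
            state_labels=("x1", "x2"),
            action_labels=("a1", "a2", "a3"),
            transitions=_NUISANCE_P,
            returns=_NUISANCE_R,
            discount=0.9,
            horizon=INFINITE,
            name="nuisance_mdp",
        )
    if name == "nuisance_obs_pomdp":
        return DecisionProcessSpec(
            state_labels=("x1", "x2"),
            action_labels=("a1", "a2", "a3"),
            transitions=_NUISANCE_P,
            returns=_NUISANCE_R,
            discount=0.9,
            horizon=INFINITE,
            observation_labels=("o1", "o2", "o3"),
            observations=_NUISANCE_F,
            name="nuisance_obs_pomdp",
        )
    if name == "two_action_backcast_fixture":
        return BackcastFixture(
            returns=_BACKCAST_RETURNS.copy(), lines=dict(_BACKCAST_LINES)
        )
    if name == "waterfowl_demo":
        from .sim_eval import waterfowl_fixture

        return waterfowl_fixture()
    raise KeyError(f"unknown example {name!r}; available: {', '.join(_EXAMPLE_NAMES)}")
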