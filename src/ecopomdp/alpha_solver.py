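"""Exact POMDP value iteration with alpha-vectors.

The finite-horizon optimal value function of a POMDP is piecewise linear and
convex (PWLC) over the belief simplex: V_t(b) = max_{alpha in L_t} b . alpha,
where each alpha-vector carries the state-specific value of one conditional
plan and the root action of that plan.  Working backward from the terminal
set L_T = {R_a} (pruned), each earlier set is produced by a full
enumeration backup: for every action a and every assignment of one
successor vector to each observation o', the candidate

    g(x) = R(a|x) + lambda * sum_o' sum_x' P(x'|x,a) f(o'|x',a) alpha_o'(x')

is formed, and the union over actions is pruned.  Pruning removes vectors
with no witness belief — first a pointwise-dominance pass, then an exact
linear-program witness test per survivor.

Infinite discounted horizons are approximated by repeating the backup until
the sup-norm change of the value on a fixed belief lattice falls below a
tolerance; the standard contraction bound eps*lambda/(1-lambda) on the
remaining error is reported alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model_core import DecisionProcessSpec, PolicyTree, as_belief, EXTENDED

__all__ = [
    "AlphaVector",
    "AlphaSet",
    "terminal_alpha_set",
    "backcast",
    "backup",
    "backup_extended",
    "prune",
    "value_at",
    "values_on_grid",
    "belief_grid",
    "stage_value_from_backcasts",
    "solve_finite_pomdp",
    "solve_infinite_pomdp",
    "InfiniteHorizonSolution",
    "extract_policy_tree",
    "belief_partition",
]

logger = logging.getLogger(__name__)

#: enumeration guard: |A| * |L|^|O| candidates beyond this raises
DEFAULT_CANDIDATE_CAP = 10 ** 6
#: componentwise tolerance below which enumerated vectors are duplicates
DEDUP_TOLERANCE = 1e-10
#: strict-improvement slack for the witness linear program
WITNESS_SLACK = 1e-9


@dataclass(eq=False)
class AlphaVector:
    """One linear piece of the PWLC value function.

    ``components[x]`` is the value of the underlying conditional plan when
    the true state is x; ``action`` is the plan's root action (an index into
    the spec's action labels); ``successor_choice`` maps each observation
    index to the index of the chosen successor vector in the next-epoch set,
    enabling full plan reconstruction.
    """

    components: np.ndarray
    action: int
    successor_choice: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)


@dataclass(eq=False)
class AlphaSet:
    """A finite set of alpha-vectors for one epoch (or the stationary limit)."""

    vectors: list[AlphaVector]
    epoch: int | str = "stationary"

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([v.components for v in self.vectors])

    @property
    def actions(self) -> np.ndarray:
        return np.array([v.action for v in self.vectors], dtype=int)


def value_at(b, L: AlphaSet) -> tuple[float, str | int, int]:
    """Optimal value, root action index and argmax-vector index at belief b.

    Ties are broken toward the lowest action index, then the lowest vector
    index.
    """
    if len(L) == 0:
        raise ValueError("empty alpha set")
    p = as_belief(b)
    scores = L.matrix @ p
    best = scores.max()
    tol = 1e-12 * (1.0 + abs(best))
    tied = np.flatnonzero(scores >= best - tol)
    k = min(tied, key=lambda i: (L.vectors[i].action, i))
    return float(scores[k]), int(L.vectors[k].action), int(k)


def values_on_grid(L: AlphaSet, grid: np.ndarray) -> np.ndarray:
    """Max-over-vectors value at each row of a (n_points, |X|) belief grid."""
    return (grid @ L.matrix.T).max(axis=1)


def belief_grid(n_states: int, n_points: int = 1001) -> np.ndarray:
    """A fixed belief lattice: ``n_points`` evenly spaced beliefs for two
    states, or a regular simplex lattice for three or more (``n_points``
    then counts divisions per axis)."""
    if n_states == 1:
        return np.ones((1, 1))
    if n_states == 2:
        b = np.linspace(0.0, 1.0, n_points)
        return np.column_stack([b, 1.0 - b])
    k = max(2, int(round(n_points ** (1.0 / (n_states - 1)))))
    pts = [
        np.array(c, dtype=float) / k
        for c in itertools.product(range(k + 1), repeat=n_states)
        if sum(c) == k
    ]
    return np.array(pts)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _prune_core(mat: np.ndarray, actions: np.ndarray,
                slack: float = WITNESS_SLACK) -> list[int]:
    """Indices (into ``mat``) of the vectors surviving pruning.

    The result is ordered by root action (stable), matching the tie-break
    convention of :func:`value_at`.
    """
    n, d = mat.shape
    if n == 0:
        return []
    order = np.argsort(actions, kind="stable")
    mat_s = mat[order]
    # dedup within DEDUP_TOLERANCE buckets, earliest (lowest-action) wins
    key = np.round(mat_s / DEDUP_TOLERANCE).astype(np.int64)
    _, first = np.unique(key, axis=0, return_index=True)
    rel = np.sort(first)
    mat_s = mat_s[rel]
    idx = order[rel]
    if len(idx) == 1:
        return [int(idx[0])]
    if d == 1:
        return [int(idx[int(np.argmax(mat_s[:, 0]))])]
    if d == 2:
        return [int(idx[i]) for i in _envelope_keep(mat_s)]
    keep = _dominance_keep(mat_s)
    mat_s, idx = mat_s[keep], idx[keep]
    rel_kept = _lark_keep(mat_s, actions[idx], slack)
    return [int(idx[i]) for i in sorted(rel_kept)]


def _dominance_keep(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of vectors not weakly dominated by another (chunked)."""
    n = len(mat)
    keep = np.ones(n, dtype=bool)
    chunk = max(1, 10_000_000 // (n * mat.shape[1] + 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ge = np.all(mat[None, :, :] >= mat[lo:hi, None, :], axis=2)
        gt = np.any(mat[None, :, :] > mat[lo:hi, None, :], axis=2)
        keep[lo:hi] &= ~(ge & gt).any(axis=1)
    return keep


def _envelope_keep(mat: np.ndarray) -> list[int]:
    """Exact upper envelope of value lines over b = Pr(first state).

    Each 2-component vector is the line ``value(b) = a2 + (a1 - a2) b``; a
    vector survives iff it is the strict maximum on a subinterval of [0, 1]
    of positive length.  O(n log n), no linear programs.
    """
    lines = [(mat[i, 0] - mat[i, 1], mat[i, 1], i) for i in range(len(mat))]
    lines.sort(key=lambda t: (t[0], -t[1], t[2]))
    # group slopes equal to within floating noise (consecutive gaps below
    # tolerance) and keep only the highest intercept per group, earliest
    # index on ties
    filtered: list[tuple[float, float, int]] = []
    k = 0
    while k < len(lines):
        j = k
        best = lines[k]
        while j + 1 < len(lines) and lines[j + 1][0] - lines[j][0] < 1e-12 * (
            1.0 + abs(lines[j][0])
        ):
            j += 1
            m_j, c_j, i_j = lines[j]
            if (c_j, -i_j) > (best[1], -best[2]):
                best = lines[j]
        filtered.append(best)
        k = j + 1

    # convex-hull scan: stack of (slope, intercept, index, start_b)
    stack: list[tuple[float, float, int, float]] = []
    for m, c, i in filtered:
        start = -np.inf
        while stack:
            m0, c0, _, s0 = stack[-1]
            x = (c0 - c) / (m - m0)  # new line above for b > x
            if x <= s0 + 1e-15:
                stack.pop()
                continue
            start = x
            break
        if not stack:
            start = -np.inf
        stack.append((m, c, i, start))

    kept = []
    for j, (_, _, i, s) in enumerate(stack):
        end = stack[j + 1][3] if j + 1 < len(stack) else np.inf
        if max(s, 0.0) < min(end, 1.0) - 1e-15:
            kept.append(i)
    kept.sort()
    return kept


def _witness(v: np.ndarray, others: np.ndarray) -> tuple[float, np.ndarray]:
    """Best strict margin of v over all of ``others`` at any belief.

    Solves  max_{b in simplex, eps}  eps  s.t.  b.(v - w) >= eps  for all w;
    the optimum is > 0 iff v is strictly maximal at some belief.  Returns
    the margin and the maximizing (witness) belief.
    """
    n = len(v)
    m = len(others)
    # variables: b (n), eps ; minimize -eps
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.hstack([others - v[None, :], np.ones((m, 1))])
    b_ub = np.zeros(m)
    A_eq = np.hstack([np.ones((1, n)), np.zeros((1, 1))])
    b_eq = np.ones(1)
    span = float(np.max(np.abs(others - v[None, :]))) + 1.0
    bounds = [(0.0, 1.0)] * n + [(-span, span)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"witness LP failed: {res.message}")
    b_star = np.clip(res.x[:n], 0.0, None)
    b_star /= b_star.sum()
    return float(-res.fun), b_star


def _lark_keep(mat: np.ndarray, actions: np.ndarray, slack: float) -> list[int]:
    """Witness filtering for 3+ states: grow the kept set by repeatedly
    testing agenda vectors for a witness belief against it."""
    n, d = mat.shape
    kept: list[int] = []
    for x in range(d):  # seed with the vertex-optimal vectors
        i = int(np.argmax(mat[:, x]))
        if i not in kept:
            kept.append(i)
    agenda = [i for i in range(n) if i not in kept]
    while agenda:
        i = agenda.pop(0)
        margin, b_star = _witness(mat[i], mat[kept])
        if margin <= slack:
            continue
        # admit the best vector at the witness belief (lowest action wins)
        pool = [i] + agenda
        scores = mat[pool] @ b_star
        best = scores.max()
        tied = [k for k in range(len(pool))
                if scores[k] >= best - 1e-12 * (1 + abs(best))]
        j = pool[min(tied, key=lambda k: (actions[pool[k]], pool[k]))]
        kept.append(j)
        if j != i:
            agenda.remove(j)
            agenda.insert(0, i)  # re-examine i against the grown kept set
    return kept


def prune(L: AlphaSet, slack: float = WITNESS_SLACK) -> AlphaSet:
    """Remove vectors that are maximal at no belief.

    After deduplication and a pointwise-dominance pass, survivors face an
    exact witness test: a vector is kept only if it strictly exceeds all
    others (by more than ``slack``) at some belief.  For two-state problems
    the witness test is the exact upper envelope of value lines; for three
    or more states it is a linear feasibility program per survivor.  The
    max-over-vectors value is unchanged at every belief.
    """
    if len(L) == 0:
        return AlphaSet([], L.epoch)
    kept = _prune_core(L.matrix, L.actions, slack)
    return AlphaSet([L.vectors[i] for i in kept], L.epoch)


# ---------------------------------------------------------------------------
# Backup
# ---------------------------------------------------------------------------

def terminal_alpha_set(spec: DecisionProcessSpec) -> AlphaSet:
    """Terminal-epoch set: the return vectors R_a surviving pruning, so that
    V_T(b) = max_a sum_x b(x) R(a|x)."""
    vectors = [
        AlphaVector(spec.returns[a], a) for a in range(spec.n_actions)
    ]
    return prune(AlphaSet(vectors, epoch="T"))


def backcast(alpha, a, o, spec: DecisionProcessSpec) -> np.ndarray:
    """Transform a next-epoch vector back through one (action, observation):

        g(x) = sum_x' P(x'|x,a) f(o'|x',a) alpha(x').

    Standard timing only.
    """
    if spec.timing == EXTENDED:
        raise ValueError("backcast is defined for standard timing")
    comp = alpha.components if isinstance(alpha, AlphaVector) else np.asarray(alpha, float)
    ai = a if isinstance(a, (int, np.integer)) else spec.action_index(a)
    oi = o if isinstance(o, (int, np.integer)) else spec.observation_index(o)
    return spec.transitions[ai] @ (spec.observations[ai][:, oi] * comp)


def _cross_sum(base: np.ndarray, per_obs: list[np.ndarray], discount: float
               ) -> np.ndarray:
    """All ``base + discount * sum_o per_obs[o][choice_o]`` combinations.

    Row layout: the choice for observation 0 varies slowest, matching
    ``np.unravel_index`` with shape ``(n_next,) * n_obs``.
    """
    nx = len(base)
    S = base[None, :]
    for G in per_obs:
        S = (S[:, None, :] + discount * G[None, :, :]).reshape(-1, nx)
    return S


def _check_cap(spec: DecisionProcessSpec, n_next: int, cap: int) -> None:
    n_cand = spec.n_actions * n_next ** spec.n_observations
    if n_cand > cap:
        raise MemoryError(
            f"enumeration backup would generate {n_cand} candidate vectors "
            f"(cap {cap}); the problem is too large for exact enumeration"
        )


def _assemble(spec, mats, L_next, epoch) -> AlphaSet:
    """Prune stacked per-action candidate matrices and rebuild vectors."""
    mat = np.vstack(mats)
    n_per_action = len(L_next) ** spec.n_observations
    actions = np.repeat(np.arange(spec.n_actions), n_per_action)
    kept = _prune_core(mat, actions)
    shape = (len(L_next),) * spec.n_observations
    vectors = []
    for i in kept:
        a, flat = divmod(i, n_per_action)
        choice = tuple(int(c) for c in np.unravel_index(flat, shape)) if shape else ()
        vectors.append(AlphaVector(mat[i], int(a), successor_choice=choice))
    return AlphaSet(vectors, epoch=epoch)


def backup(
    L_next: AlphaSet, spec: DecisionProcessSpec, cap: int = DEFAULT_CANDIDATE_CAP
) -> AlphaSet:
    """One exact dynamic-programming step L_{t+1} -> L_t (standard timing).

    Full Monahan-style enumeration over actions and per-observation
    successor assignments, followed by pruning.  The resulting set's upper
    envelope is the Bellman one-step-lookahead value at every belief.
    """
    if spec.timing == EXTENDED:
        raise ValueError("extended-timing spec: use backup_extended")
    if len(L_next) == 0:
        raise ValueError("empty successor set")
    _check_cap(spec, len(L_next), cap)
    Vmat = L_next.matrix
    mats = []
    for a in range(spec.n_actions):
        P, f = spec.transitions[a], spec.observations[a]
        per_obs = [
            (Vmat * f[:, o]) @ P.T for o in range(spec.n_observations)
        ]  # row v: backcast g(x) = sum_x' P(x'|x,a) f(o'|x',a) alpha_v(x')
        mats.append(_cross_sum(spec.returns[a], per_obs, spec.discount))
    epoch = L_next.epoch - 1 if isinstance(L_next.epoch, int) else L_next.epoch
    return _assemble(spec, mats, L_next, epoch)


def backup_extended(
    L_next: AlphaSet, spec: DecisionProcessSpec, cap: int = DEFAULT_CANDIDATE_CAP
) -> AlphaSet:
    """Backup under extended timing (observation before the transition).

    Candidates use prior-state observation weights and (optionally)
    observation-conditioned transitions:

        g(x) = R(a|x) + lambda * sum_o f(o|x,a) sum_x' P(x'|x,a,o) alpha_o(x').
    """
    if spec.timing != EXTENDED:
        raise ValueError("spec timing is not extended")
    if len(L_next) == 0:
        raise ValueError("empty successor set")
    _check_cap(spec, len(L_next), cap)
    Vmat = L_next.matrix
    mats = []
    for a in range(spec.n_actions):
        f = spec.observations[a]
        per_obs = []
        for o in range(spec.n_observations):
            P = (
                spec.transitions[a, o]
                if spec.transitions.ndim == 4
                else spec.transitions[a]
            )
            per_obs.append((Vmat @ P.T) * f[:, o])
        mats.append(_cross_sum(spec.returns[a], per_obs, spec.discount))
    epoch = L_next.epoch - 1 if isinstance(L_next.epoch, int) else L_next.epoch
    return _assemble(spec, mats, L_next, epoch)


def _backup_dispatch(L_next, spec, cap):
    if spec.timing == EXTENDED:
        return backup_extended(L_next, spec, cap)
    return backup(L_next, spec, cap)


# ---------------------------------------------------------------------------
# Stage valuation from tabulated backcast lines (two-state problems)
# ---------------------------------------------------------------------------

def stage_value_from_backcasts(
    b,
    returns,
    lines: dict[tuple[str, str, str], tuple[float, float]],
    discount: float,
    action_labels=None,
    observation_labels=None,
) -> tuple[float, str]:
    """One stage of POMDP valuation from per-(action, action, observation)
    backcast value lines over a scalar belief.

    ``b`` is Pr(x1) (a scalar, or a 2-state belief whose first entry is
    used); ``returns`` maps each prior action to its (R(a|x1), R(a|x2))
    return pair (a mapping, or an array ordered like ``action_labels``);
    each ``lines[(a_prior, a_next, o)]`` is an ``(intercept, slope)`` pair
    giving a next-stage value linear in b.  Per observation the lines are
    maximized over the next action, summed over observations, discounted,
    and added to the belief-averaged immediate return; the prior action
    maximizing the total (ties to the lowest index) is returned with the
    value.
    """
    if np.ndim(b) == 1:
        b = as_belief(b, 2)[0]
    b = float(b)
    if isinstance(returns, dict):
        if action_labels is None:
            action_labels = tuple(returns)
        R = np.array([returns[a] for a in action_labels], dtype=float)
    else:
        R = np.asarray(returns, dtype=float)
        if action_labels is None:
            action_labels = tuple(sorted({k[0] for k in lines}))
    if observation_labels is None:
        observation_labels = tuple(sorted({k[2] for k in lines}))
    next_actions = tuple(sorted({k[1] for k in lines}))

    best_val, best_action = -np.inf, None
    for i, a_prior in enumerate(action_labels):
        total = 0.0
        for o in observation_labels:
            vals = []
            for a_next in next_actions:
                key = (a_prior, a_next, o)
                if key not in lines:
                    raise KeyError(f"missing backcast line for {key}")
                c, s = lines[key]
                vals.append(c + s * b)
            total += max(vals)
        immediate = b * R[i, 0] + (1.0 - b) * R[i, 1]
        v = immediate + discount * total
        if v > best_val + 1e-12:
            best_val, best_action = v, a_prior
    return float(best_val), str(best_action)


# ---------------------------------------------------------------------------
# Finite and infinite horizon drivers
# ---------------------------------------------------------------------------

def solve_finite_pomdp(
    spec: DecisionProcessSpec,
    horizon: int | None = None,
    cap: int = DEFAULT_CANDIDATE_CAP,
) -> list[AlphaSet]:
    """Alpha-vector sets for epochs T, T-1, ..., T-(horizon-1).

    The first element is the terminal set; each later element is obtained
    from its predecessor by one enumeration backup.
    """
    h = spec.horizon if horizon is None else horizon
    if h == "infinite":
        raise ValueError("infinite horizon: use solve_infinite_pomdp")
    h = int(h)
    if h < 1:
        raise ValueError("horizon must be >= 1")
    L = terminal_alpha_set(spec)
    L.epoch = 0
    sets = [L]
    for _ in range(h - 1):
        L = _backup_dispatch(L, spec, cap)
        sets.append(L)
        logger.info("epoch %s: %d alpha-vectors", L.epoch, len(L))
    for k, s in enumerate(sets):
        s.epoch = "T" if k == 0 else f"T-{k}"
    return sets


@dataclass
class InfiniteHorizonSolution:
    """Stationary alpha set with the convergence diagnostics of the run."""

    alpha_set: AlphaSet
    sup_change: float        # last sup-norm change on the belief lattice
    error_bound: float       # contraction bound lambda*eps/(1-lambda)
    iterations: int


def solve_infinite_pomdp(
    spec: DecisionProcessSpec,
    epsilon: float = 1e-6,
    max_iterations: int = 10 ** 4,
    grid_points: int = 1001,
    cap: int = DEFAULT_CANDIDATE_CAP,
) -> InfiniteHorizonSolution:
    """Approximate the stationary value function by repeated backups.

    Stops when the sup-norm change of the upper envelope on a fixed belief
    lattice falls below ``epsilon`` (immediately after one pass when the
    discount is zero).  The guaranteed remaining error is bounded by
    ``epsilon * lambda / (1 - lambda)`` on the lattice.
    """
    if spec.discount >= 1.0:
        raise ValueError("infinite-horizon solution requires discount < 1")
    grid = belief_grid(spec.n_states, grid_points)
    L = terminal_alpha_set(spec)
    v = values_on_grid(L, grid)
    if spec.discount == 0.0:
        return InfiniteHorizonSolution(L, 0.0, 0.0, 0)
    for it in range(1, max_iterations + 1):
        L = _backup_dispatch(L, spec, cap)
        v_new = values_on_grid(L, grid)
        change = float(np.max(np.abs(v_new - v)))
        v = v_new
        if change < epsilon:
            bound = change * spec.discount / (1.0 - spec.discount)
            L.epoch = "stationary"
            return InfiniteHorizonSolution(L, change, bound, it)
    raise RuntimeError(
        f"no convergence below {epsilon} within {max_iterations} backups "
        f"(last change {change:.3g})"
    )


# ---------------------------------------------------------------------------
# Policy extraction
# ---------------------------------------------------------------------------

def extract_policy_tree(sets: list[AlphaSet], b0, spec: DecisionProcessSpec) -> PolicyTree:
    """The conditional plan implied by the maximizing vector at belief b0.

    ``sets`` is the output of :func:`solve_finite_pomdp` (epochs T first);
    the plan is rooted at the earliest epoch and follows each vector's
    ``successor_choice`` pointers forward in time.
    """
    _, _, k = value_at(b0, sets[-1])

    def build(level: int, idx: int) -> PolicyTree:
        vec = sets[level].vectors[idx]
        node = PolicyTree(
            root_action=spec.action_labels[vec.action], depth=level + 1
        )
        if level > 0 and vec.successor_choice is not None:
            node.branches = {
                spec.observation_labels[o]: build(level - 1, j)
                for o, j in enumerate(vec.successor_choice)
            }
        return node

    return build(len(sets) - 1, k)


def belief_partition(L: AlphaSet, spec: DecisionProcessSpec) -> list[dict]:
    """For a two-state problem, the belief-interval partition of [0, 1]
    (b = Pr of the first state) with the optimal action per segment."""
    if spec.n_states != 2:
        raise ValueError("belief partition is defined for two-state problems")
    grid = belief_grid(2, 2001)
    idx = np.argmax(grid @ L.matrix.T, axis=1)
    segments = []
    start = 0
    for i in range(1, len(grid) + 1):
        if i == len(grid) or idx[i] != idx[start]:
            k = idx[start]
            segments.append(
                {
                    "b_low": float(grid[start, 0]),
                    "b_high": float(grid[i - 1, 0]),
                    "action": spec.action_labels[L.vectors[k].action],
                    "vector": k,
                }
            )
            start = i
    return segments
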