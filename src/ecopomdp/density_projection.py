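"""Density projection for continuous-state belief approximation.

A continuous belief (the manager's distribution over, e.g., population
density) rarely stays in a convenient family once pushed through dynamics
and Bayes' rule.  Density projection replaces each posterior with the member
of a fixed exponential family whose expected sufficient statistics match the
target's — the member minimizing the Kullback-Leibler divergence
KL(target || proxy).  Beliefs are then summarized by a few parameters, the
parameter space is discretized on a grid, and a nearest-neighbor rule turns
simulated belief updates into a finite Markov decision process over grid
nodes that the ordinary MDP machinery can solve.

Two univariate families are supported:

* ``gaussian`` — sufficient statistics (x, x^2); parameters (mean, variance).
* ``beta`` — sufficient statistics (log x, log(1-x)); parameters (a, b),
  recovered from the expected log-moments via the digamma equations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize, special, stats

from .model_core import DecisionProcessSpec, INFINITE

__all__ = [
    "ProjectionFamily",
    "GAUSSIAN",
    "BETA",
    "ParameterGrid",
    "project_moment_match",
    "kl_divergence",
    "build_projected_process",
]


@dataclass(frozen=True)
class ProjectionFamily:
    """A parametric family available as a projection target."""

    name: str  # "gaussian" or "beta"

    @property
    def n_params(self) -> int:
        return 2

    @property
    def support(self) -> tuple[float, float]:
        return (-np.inf, np.inf) if self.name == "gaussian" else (0.0, 1.0)

    @property
    def param_bounds(self) -> tuple[tuple[float, float], ...]:
        if self.name == "gaussian":
            return ((-np.inf, np.inf), (1e-12, np.inf))  # (mean, variance)
        return ((1e-8, np.inf), (1e-8, np.inf))  # (a, b)

    # -- sufficient statistics -------------------------------------------
    def sufficient_stats(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.name == "gaussian":
            return np.stack([x, x * x])
        return np.stack([np.log(x), np.log1p(-x)])

    def params_from_stats(self, stats_mean: np.ndarray) -> tuple[float, float]:
        """Invert expected sufficient statistics to family parameters."""
        if self.name == "gaussian":
            m, m2 = stats_mean
            var = m2 - m * m
            if var <= 0:
                raise ValueError(f"degenerate target: variance {var:.3g} <= 0")
            return float(m), float(var)
        return _beta_from_log_moments(stats_mean[0], stats_mean[1])

    def stats_from_params(self, params: Sequence[float]) -> np.ndarray:
        if self.name == "gaussian":
            m, v = params
            return np.array([m, v + m * m])
        a, b = params
        return np.array(
            [
                special.digamma(a) - special.digamma(a + b),
                special.digamma(b) - special.digamma(a + b),
            ]
        )

    # -- distribution interface ------------------------------------------
    def frozen(self, params: Sequence[float]):
        if self.name == "gaussian":
            m, v = params
            return stats.norm(m, np.sqrt(v))
        return stats.beta(*params)

    def pdf(self, x, params) -> np.ndarray:
        return self.frozen(params).pdf(x)

    def sample(self, params, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.name == "gaussian":
            m, v = params
            return rng.normal(m, np.sqrt(v), size=n)
        a, b = params
        return rng.beta(a, b, size=n)


GAUSSIAN = ProjectionFamily("gaussian")
BETA = ProjectionFamily("beta")


def _beta_from_log_moments(e_logx: float, e_log1mx: float) -> tuple[float, float]:
    """Solve digamma(a) - digamma(a+b) = E[log x] (and its mirror) for (a, b)."""
    # moment-style initial guess via the implied mean
    mean0 = 1.0 / (1.0 + np.exp(e_log1mx - e_logx))
    guess = np.log([max(mean0 * 5.0, 0.1), max((1 - mean0) * 5.0, 0.1)])

    def eqs(logab):
        a, b = np.exp(logab)
        d = special.digamma(a + b)
        return [
            special.digamma(a) - d - e_logx,
            special.digamma(b) - d - e_log1mx,
        ]

    sol = optimize.root(eqs, guess, method="hybr", tol=1e-12)
    # hybr may stop on step-size grounds while the residual is already tiny
    if np.max(np.abs(sol.fun)) > 1e-9:
        raise ValueError(f"beta projection failed to invert log-moments: {sol.message}")
    a, b = np.exp(sol.x)
    return float(a), float(b)


def _expected_stats(target, family: ProjectionFamily) -> np.ndarray:
    """Expected sufficient statistics of the target under the family's stats.

    ``target`` may be a weighted sample ``(values, weights)``, a bare sample
    array, a frozen scipy distribution, or a ``(pdf, (lo, hi))`` pair for
    quadrature.
    """
    if isinstance(target, tuple) and len(target) == 2 and callable(target[0]):
        pdf, (lo, hi) = target
        out = []
        for i in range(family.n_params):
            val, _ = integrate.quad(
                lambda x, i=i: family.sufficient_stats(np.array([x]))[i, 0] * pdf(x),
                lo,
                hi,
                limit=200,
            )
            out.append(val)
        return np.array(out)
    if hasattr(target, "pdf") and hasattr(target, "support"):
        lo, hi = target.support()
        return _expected_stats((target.pdf, (lo, hi)), family)
    if isinstance(target, tuple) and len(target) == 2:
        values, weights = np.asarray(target[0], float), np.asarray(target[1], float)
        w = weights / weights.sum()
        return family.sufficient_stats(values) @ w
    values = np.asarray(target, dtype=float)
    return family.sufficient_stats(values).mean(axis=1)


def project_moment_match(target, family: ProjectionFamily) -> tuple[float, float]:
    """Parameters of the family member matching the target's expected
    sufficient statistics (the KL(target || proxy) minimizer for
    exponential families).

    ``target`` may be a weighted sample ``(values, weights)``, a plain
    sample array, a frozen scipy.stats distribution, or a ``(pdf, (lo, hi))``
    density/support pair integrated by quadrature.
    """
    stats_mean = _expected_stats(target, family)
    if not np.all(np.isfinite(stats_mean)):
        raise ValueError(f"target moments not finite: {stats_mean}")
    params = family.params_from_stats(stats_mean)
    for p, (lo, hi) in zip(params, family.param_bounds):
        if not (lo <= p <= hi):
            raise ValueError(f"projected parameter {p:.4g} outside bounds ({lo}, {hi})")
    return params


def kl_divergence(target_pdf: Callable, support: tuple[float, float],
                  family: ProjectionFamily, params) -> float:
    """KL(target || family member) by quadrature (for diagnostics/tests)."""
    proxy = family.frozen(params)

    def integrand(x):
        p = target_pdf(x)
        if p <= 0:
            return 0.0
        q = proxy.pdf(x)
        return p * (np.log(p) - np.log(max(q, 1e-300)))

    val, _ = integrate.quad(integrand, *support, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# Parameter grids and the projected proxy process
# ---------------------------------------------------------------------------

@dataclass
class ParameterGrid:
    """A finite lattice of family parameter tuples."""

    nodes: np.ndarray  # (n_nodes, n_params)
    spacing: np.ndarray  # per-dimension spacing

    def __post_init__(self) -> None:
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        self.spacing = np.asarray(self.spacing, dtype=float)
        if len(self.nodes) == 0:
            raise ValueError("empty parameter grid")

    @classmethod
    def regular(cls, bounds: Sequence[tuple[float, float]], counts: Sequence[int]
                ) -> "ParameterGrid":
        axes = [np.linspace(lo, hi, int(n)) for (lo, hi), n in zip(bounds, counts)]
        nodes = np.array(list(itertools.product(*axes)))
        spacing = np.array(
            [
                (hi - lo) / (n - 1) if n > 1 else max(hi - lo, 1.0)
                for (lo, hi), n in zip(bounds, counts)
            ]
        )
        return cls(nodes, spacing)

    def nearest(self, params) -> int:
        """Nearest node index (spacing-scaled Euclidean); raises if the
        parameters fall outside the lattice hull by more than one cell."""
        p = np.asarray(params, dtype=float)
        z = (self.nodes - p) / self.spacing
        i = int(np.argmin((z * z).sum(axis=1)))
        if np.any(np.abs(self.nodes[i] - p) > 1.5 * self.spacing):
            raise ValueError(
                f"projected parameters {tuple(p)} fall outside the parameter grid"
            )
        return i

    def __len__(self) -> int:
        return len(self.nodes)


def build_projected_process(
    transition_sampler: Callable,
    observation_sampler: Callable | None,
    family: ProjectionFamily,
    grid: ParameterGrid,
    action_labels: Sequence[str],
    n_mc: int = 10_000,
    seed: int = 0,
    return_fn: Callable | None = None,
    n_observation_cells: int | None = None,
    discount: float = 0.95,
) -> DecisionProcessSpec:
    """Monte-Carlo construction of a discrete belief-MDP over parameter nodes.

    Each grid node stands for a belief summarized by family parameters.  Per
    node and action, ``n_mc`` states are drawn from the node's distribution
    and pushed through ``transition_sampler(x, action, rng) -> x'``; if an
    ``observation_sampler(x', action, rng) -> int`` is given, the samples are
    partitioned by observation cell, and each cell's weighted posterior
    sample is projected back to the family and mapped to the nearest node.
    Cell frequencies become the node-to-node transition probabilities (rows
    sum to 1 by construction).  ``return_fn(x, action)`` is averaged per node
    to give R(a|node).  The result is an observable MDP over nodes, solvable
    by the standard dynamic-programming module.
    """
    rng = np.random.default_rng(seed)
    na, ng = len(action_labels), len(grid)
    P = np.zeros((na, ng, ng))
    R = np.zeros((na, ng))
    for g in range(ng):
        params = tuple(grid.nodes[g])
        for a, al in enumerate(action_labels):
            x = family.sample(params, n_mc, rng)
            x_next = np.asarray(transition_sampler(x, al, rng), dtype=float)
            if return_fn is not None:
                R[a, g] = float(np.mean(return_fn(x, al)))
            if observation_sampler is None:
                cells = np.zeros(len(x_next), dtype=int)
                n_cells = 1
            else:
                cells = np.asarray(observation_sampler(x_next, al, rng), dtype=int)
                n_cells = (
                    n_observation_cells
                    if n_observation_cells is not None
                    else int(cells.max()) + 1
                )
            for c in range(n_cells):
                mask = cells == c
                w = mask.mean()
                if w == 0.0:
                    continue
                post_params = project_moment_match(x_next[mask], family)
                P[a, g, grid.nearest(post_params)] += w
    labels = tuple(
        "node(" + ", ".join(f"{v:.6g}" for v in node) + ")" for node in grid.nodes
    )
    return DecisionProcessSpec(
        state_labels=labels,
        action_labels=tuple(action_labels),
        transitions=P,
        returns=R,
        discount=discount,
        horizon=INFINITE,
        name="projected_belief_mdp",
    )
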