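# Methods

`ecopomdp` implements the decision-theoretic machinery for managing
ecological systems whose state is only partially observed: finite Markov
decision processes (MDPs) and partially observable MDPs (POMDPs), exact
solvers for both, mixed-observability and hidden-model extensions used in
adaptive management, and a density-projection scheme for continuous states.
This note records the models, the numerical choices, and what the test suite
does and does not establish.

## Process model

A managed system is a tuple ⟨X, A, P, R, T, λ⟩: finite states X (e.g.
abundance classes), actions A, per-action transition kernels P(x′|x,a),
immediate returns R(a|x) in arbitrary management units (negative values are
costs), a discount λ ∈ (0, 1], and a horizon T (finite or infinite).
A POMDP adds finite observations O and an observation model f: the manager
never sees x, only o, and tracks a belief b — a probability vector over X
updated by Bayes' rule.

Two observation timings are supported:

* **standard** — `x, a → x′ → o′`: the observation follows the transition,
  f(o′|x′,a), and cannot influence it.  Belief update:
  b_{a,o′}(x′) ∝ f(o′|x′,a) · Σₓ b(x) P(x′|x,a).
* **extended** — `x, a → o → x′`: the observation is tied to the
  pre-transition state, f(o|x,a), and the transition may be conditioned on
  it, P(x′|x,a,o).  Belief update:
  b_{a,o}(x′) ∝ Σₓ b(x) f(o|x,a) P(x′|x,a,o).
  If no o-conditioned transition array is supplied, P(x′|x,a) is used for
  every o — extended timing merely *allows* the dependence.

Zero-probability observations raise an error rather than silently
renormalising 0/0: in simulation they cannot occur by construction, so their
appearance indicates a model error.

## Solvers

**Observable MDPs.**  Finite horizons use backward induction on the Bellman
equation, V_t(x) = max_a [R(a|x) + λ Σ P(x′|x,a) V_{t+1}(x′)], with the
terminal epoch V_T(x) = max_a R(a|x).  Per-action candidate values are
retained alongside the optima.  Infinite discounted horizons use policy
iteration: closed-form evaluation V_π = (I − λP_π)⁻¹R_π (a dense linear
solve; residual checked to 1e-8) alternated with greedy improvement,
starting from the myopic policy argmax_a R(a|x) and keeping the incumbent
action on value ties so the loop terminates.  Ties in every maximisation
break toward the lowest action index, making policies reproducible.

**POMDPs.**  The finite-horizon optimal value function is piecewise linear
and convex over the belief simplex: V_t(b) = max_{α ∈ L_t} b·α, where each
α-vector carries state-specific values of one conditional plan.  The solver
uses full enumeration backups (Monahan): for each action and each assignment
of a successor vector to each observation, form
R_a + λ Σ_{o′} g_{a,o′}, with the backcast
g_{a,o′}(x) = Σ_{x′} P(x′|x,a) f(o′|x′,a) α_{o′}(x′)
(prior-state weights f(o|x,a) and o-conditioned transitions under extended
timing), then prune the union.  A guard rejects backups whose candidate
count |A|·|L|^{|O|} exceeds a configurable cap (default 10⁶).  Incremental
pruning, the witness algorithm, point-based methods and policy graphs are
deliberately out of scope; enumeration-plus-pruning is adequate at the scale
of the worked examples this package targets.

**Pruning** removes vectors that are maximal at no belief.  After
deduplication (componentwise 1e-10) and a pointwise-dominance pass, the
witness test is exact:

* two states — the upper envelope of value lines over b = Pr(x₁) is computed
  by a convex-hull scan in O(n log n); a vector survives iff it is the
  strict maximum on a subinterval of [0, 1] of positive length.  Slopes
  equal to within relative 1e-12 are grouped and only the highest intercept
  kept (floating-point noise in the last ulp otherwise scrambles the
  equal-slope ordering).
* three or more states — per-survivor linear programs (HiGHS via SciPy):
  maximise ε subject to b·(α − α′) ≥ ε for all rivals over the simplex; a
  vector is kept iff ε* exceeds a strict-improvement slack of 1e-9.  The
  kept set is grown Lark-style, seeding with the vertex-optimal vectors and
  admitting the best vector at each discovered witness belief.

**Infinite-horizon POMDPs** repeat the backup until the sup-norm change of
the envelope on a fixed belief lattice (1,001 points for two states, a
regular simplex lattice otherwise) falls below ε (default 1e-6); the
contraction bound ελ/(1−λ) on the remaining error is reported with the
solution.  Sup-norm over the continuum is not computable; the lattice is the
documented compromise, and a residual test backs it up.

## Mixed observability and adaptive management

A hidden-model MDP (hmMDP) — the skeleton of adaptive management — has an
observed state x but uncertain dynamics: one of several models y governs
P(x′|x,a,y), tracked by a model belief b_y.  Each observed transition
updates the belief by per-model likelihood weighting,
b′(y) ∝ b(y)·P(x′|x,a,y).  Valuation runs dynamic programming over
X × (a discretised model-belief simplex): a regular lattice with default
spacing 0.05, posterior beliefs projected to the nearest node.  The discount
is applied to the future term exactly as in the ordinary Bellman equation.
Model beliefs are a martingale under data generated from the mixture — a
property test checks this by Monte Carlo.

Nonstationary model structure (e.g. climate-driven drift) adds P(y′|y);
transitions from x to x′ follow the post-change model y′.  The update is
kept two-stage — a posterior over prior models, b′(y) ∝ b(y)·Σ_{y′}
P(y′|y)P_{y′}(x′|x,a), and a next-model belief marginalised over it — rather
than collapsing immediately, since both are useful to report.  With an
identity model-transition matrix the machinery reduces exactly to the
stationary update (tested).

A general MOMDP composes an observable MDP and a hidden POMDP into a flat
product POMDP: independent component dynamics, observation = (x′ revealed
deterministically, o_y from the hidden model), returns added across
components.  Degenerate compositions return the surviving component
unchanged.

## Density projection for continuous states

Continuous beliefs are approximated by the member of an exponential family
matching the target's expected sufficient statistics — the
Kullback–Leibler-minimal projection.  Two univariate families are provided:
Gaussian (statistics x, x²; parameters mean and variance) and Beta
(statistics log x, log(1−x); parameters recovered from the digamma
equations by root-finding with a method-of-moments start).  Univariate
scope with two families is a deliberate restriction: it is enough to
exercise the method end to end.

A discrete proxy process is built by Monte Carlo (default 10,000 draws per
node–action cell, explicit seed): per parameter-grid node and action, states
are sampled from the node's distribution, pushed through the user's
transition sampler, partitioned by observation cell, and each cell's
posterior sample is projected and mapped to the nearest grid node
(spacing-scaled Euclidean; parameters falling more than 1.5 cells outside
the lattice raise a bounds error).  Cell frequencies become row-stochastic
node transitions, so the result is an ordinary MDP over parameter nodes.

## Simulation and Monte-Carlo validation

`sample_trajectory` realises the generative process one step at a time from
a single seed; `mc_policy_value` vectorises replicates over one seeded
generator (identical arguments give identical estimates) and truncates
infinite horizons where the relative discounted tail falls below 1e-6.
The headline cross-module check: the Monte-Carlo discounted return of the
α-solver's greedy policy matches `value_at` at the starting belief within
three standard errors at n = 20,000 replicates.

## Built-in examples and the waterfowl demonstration

The nuisance-species fixtures (two abundance states; no-investment, habitat
alteration, trapping; λ = 0.9; a three-level monitoring model) reproduce the
printed worked examples and anchor the exact-value tests.  The monitored
variant's discount is not separately specified anywhere authoritative;
0.9 is recorded as an inherited, overridable assumption.  The two-action
stage-valuation fixture stores its twelve backcast value lines as
(intercept, slope) pairs — they are inputs, since the joint probabilities
behind them are not recoverable, and only the stage-valuation operator is
tested against them.

The waterfowl-harvest fixture is a *demonstration* model, not an estimate
for any real population: an annual cycle with spring–summer survival
Ss = 0.8, recruitment 0.8 young per adult, fall harvest at a chosen rate,
and fall–winter survival Sw = 0.9, tracked in five abundance classes with
stochastic rounding and a discretised-normal observation model
(sd 0.5 classes).  Defaults give per-year growth 1.296·(1−h), so the three
harvest actions (0.1, 0.25, 0.4) straddle replacement.

## What the tests show — and don't

Exact values are verified against hand arithmetic and independent oracles:
direct recursion over the (action, observation) tree for POMDP values,
exhaustive policy enumeration for MDP optima, quadrature for projection
KL-minimality, and seeded Monte Carlo for policy values.  Oracle tests run
at deliberately small sizes (2–4 states, horizons ≤ 4 for the recursion
oracle; 20,000 simulation replicates) — sizes at which the oracles are
themselves exact or statistically sharp.  Two subtleties the suite
documents: with a single (uninformative) observation the process is
open-loop and its vertex values fall strictly below the observable MDP's
after one backup, and an extended-timing observation that reveals the prior
state delivers information one step late — in both cases equality with the
MDP holds only under deterministic transitions, and the tests assert
exactly that.

All fixtures are small and synthetic.  Passing tests establish correctness
of the machinery on finite, flat, Markovian processes; they say nothing
about model adequacy for a real population, about non-Markovian dynamics,
or about scaling beyond the enumeration guard.

## Known limitations

* Exact enumeration backups scale as |A|·|L|^{|O|}; the guard refuses
  rather than approximates.  Large problems need point-based or other
  approximate solvers, which are out of scope.
* The hmMDP grid solver's nearest-node projection introduces discretisation
  bias; the grid-refinement test checks Cauchy behaviour, not a rate.
* Density projection is univariate and Monte-Carlo based; transition rows
  inherit sampling noise of order n_mc^{-1/2}.
* Undiscounted (λ = 1) infinite-horizon criteria (average reward) are not
  supported.
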