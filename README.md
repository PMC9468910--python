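# ecopomdp

Decision-theoretic tools for managing ecological systems whose state is only
partially observed.

Ecological management — controlling an invasive species, setting harvest
regulations, conserving a cryptic population — is sequential decision making
against stochastic dynamics, usually with imperfect monitoring.  `ecopomdp`
models such problems as Markov decision processes ⟨X, A, P, R, T, λ⟩ and
their partially observable extension ⟨X, A, O, P, f, R, T, λ⟩, where the
manager tracks a *belief state* b (a probability distribution over the true
system state) updated by Bayes' rule from monitoring observations.  The
package provides:

* **model_core / fileio** — validated process specifications, YAML/JSON
  configs and the Cassandra-style `.pomdp` text format, and built-in
  nuisance-species example models;
* **mdp_dp** — backward induction V_t(x) = max_a [R(a|x) + λ Σ P(x′|x,a)
  V_{t+1}(x′)] for finite horizons and policy iteration
  V_π = (I − λP_π)⁻¹R_π for infinite ones;
* **belief_dynamics** — belief prediction, observation likelihoods and
  Bayesian updates, under both standard timing (observe after the
  transition) and extended timing (observe before it, possibly influencing
  it);
* **alpha_solver** — exact POMDP value iteration: the optimal value is the
  upper envelope max_α b·α of a finite set of α-vectors, computed by
  enumeration backups with exact pruning (upper-envelope scan for two
  states, witness linear programs otherwise), for finite and infinite
  horizons;
* **momdp_adaptive** — mixed observability and hidden-model MDPs (the
  formal skeleton of adaptive management), with stationary or drifting
  model structure;
* **density_projection** — KL-minimal moment-matching projection of
  continuous beliefs onto Gaussian/Beta families and a Monte-Carlo proxy
  MDP over a parameter grid;
* **sim_eval** — seeded trajectory simulation and vectorised Monte-Carlo
  policy valuation, the independent check on every solver.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example: nuisance-species control

Two abundance states (`x1` low, `x2` high), three actions (`a1` no
investment, `a2` habitat alteration, `a3` trap and remove), discount 0.9.

```python
import ecopomdp as ep

spec = ep.builtin_example("nuisance_mdp")
table = ep.backward_induction(spec, horizon=3)
print(table.as_frame().to_string(index=False))
```

```
epoch state action  value
    T    x1     a1 14.500
    T    x2     a2  7.500
  T-1    x1     a2 23.790
  T-1    x2     a3 17.290
  T-2    x1     a2 32.241
  T-2    x2     a3 25.741
```

At the terminal epoch it is best to do nothing when abundance is low (14.5)
and alter habitat when it is high (7.5); with more epochs ahead, habitat
alteration protects a low population and trapping knocks back a high one.
Over an infinite horizon the same stationary policy emerges with values

```python
policy, values = ep.policy_iteration(spec)
# {'x1': 'a2', 'x2': 'a3'}   [108.3 101.8]
```

Adding a three-level monitoring model (`nuisance_obs_pomdp`) makes the
abundance class latent; the exact α-vector solver then partitions belief
space by optimal action:

```python
pomdp = ep.builtin_example("nuisance_obs_pomdp")
sol = ep.solve_infinite_pomdp(pomdp, epsilon=1e-4)
v, a, _ = ep.value_at([0.5, 0.5], sol.alpha_set)
# v = 101.81, action 'a2' — alter habitat when the low/high odds are even
est, se = ep.mc_policy_value(pomdp, sol.alpha_set, [0.5, 0.5], n=20_000, seed=1)
# 101.78 ± 0.053 — simulation agrees with the solver within sampling error
```

The belief partition shows trapping is optimal only when the manager is
quite sure abundance is high (b = Pr(low) below about 0.27), habitat
alteration otherwise.

A command-line interface wraps the same machinery:

```bash
ecopomdp solve-mdp --spec model.yaml --horizon 3
ecopomdp solve-pomdp --spec model.pomdp --horizon infinite --epsilon 1e-6
ecopomdp simulate --spec model.yaml --policy x1:a2,x2:a3 --n 1000 --seed 1
ecopomdp examples
```

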