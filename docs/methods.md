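# Methods

This note records the modelling assumptions, algorithmic choices and
numerical conventions behind the package, including every place where
the underlying theory leaves the design open.

## Time and space conventions

The sensor value s₀ arrives at t = 0 and the first action a₁ is taken
at t = 1; ranges written `t:T` include both ends.  All spaces are
finite and labeled; the declared label order is semantic — it fixes
array layouts, enumeration order, and the lexicographic tie-break in
greedy selection.  All information quantities are computed with natural
logarithms and reported in nats (a bits conversion exists on output
only).  The convention 0·log 0 = 0 is applied throughout, and KL
divergence returns +∞ on an absolute-continuity violation instead of
raising, because motivation functionals may legitimately evaluate it.

Distribution constructors renormalize silently when total mass deviates
from 1 by at most 1e-9 and reject beyond that; joints must be within
1e-10 after construction.

## Memory

Agents keep a perfect memory m_t = (s₀..s_{t−1}, a₁..a_{t−1}); the
memory update is deterministic concatenation.  A deterministic agent
makes the stored actions redundant (they are a function of the rest of
the memory), but one representation serves both the stochastic and the
deterministic case, so actions are always stored.

## Parameter-belief backends

The belief over the three parameter blocks supports two backends, and
every operation declares which it accepts:

* **dirichlet** — independent Dirichlet rows per block.  Exact
  posterior computations represent the belief as a weighted mixture
  over latent trajectories ê_{<t}, each component carrying the
  conjugate counts accumulated along its trajectory.  Component weights
  are products of sequential (Pólya) predictives of the observed data;
  joint *future* predictives run the same sequential predictive with
  running counts along each enumerated future path, which is exact by
  exchangeability of the Dirichlet-multinomial.  The cost is |Ê|^t and
  is guarded by an explicit enumeration cap (default 10⁶ joint states)
  that raises rather than degrades.
* **ensemble** — a weighted finite set of concrete parameter points
  (world hypotheses).  Latent trajectories are collapsed by the scaled
  forward algorithm, leaving one component per (point, ê_{t−1}); cost
  is linear in t.

Component weights are held in log space and combined by log-sum-exp.  A
history with zero probability under the entire prior raises an error
rather than renormalizing silently.  The marginal parameter posterior
under the dirichlet backend is a *mixture of Dirichlet blocks* and is
carried as such (a third, output-only belief representation).

The latent space Ê is configurable independently of the true E; the
shipped model builders default to |Ê| = |E|.  Default hyperparameters
are flat (all concentrations 1); ensemble weights default to uniform.

## Universal-RL specialization

Setting Ê to the space of histories makes ê_{t−1} observed, so the
posterior collapses to Bayes-rule weight updates over a class of
next-sensor predictors with mixture one-step predictions.  This is
implemented directly (`url_specialize`) on predictor objects — fixed
conditional tables or per-context Dirichlet counts, whose one-step
predictive under flat concentration is the Laplace rule
(n_s+1)/(n+|S|).  The per-context predictor takes a context function;
the default (full history) never revisits a context, so coarser
contexts are available where recurrence is wanted.  A helper constructs
the explicit history-space generative model so the equivalence with the
general posterior machinery is testable on small instances.

## Variational inference

The mean-field family factorizes over past latent states and
parameters: one categorical per ê_τ plus Dirichlet blocks (or a
reweighting vector over ensemble points) for θ.  The algorithmic
choices the theory leaves open are fixed as follows:

* **Updates** — conjugate exponentiated-expected-log coordinate
  updates; expected logs use digamma differences for Dirichlet factors.
* **Sweep order** — θ blocks first, then state factors in chronological
  order; fixed for reproducibility.
* **Initialization** — deterministic from the prior (uniform state
  factors); optional seeded random restarts draw state factors from a
  flat Dirichlet.  With fully symmetric (flat) priors the deterministic
  init can sit on a label-permutation saddle; an asymmetric (e.g.
  sensor-informed) prior or random restarts break it.  This
  overconfidence/symmetry caveat of mean-field methods is inherent and
  is mitigated only by restarts here.
* **Stopping** — |ΔF| < 1e-8 per sweep, at most 500 sweeps.
* **Floors** — expected-log terms of probability-zero entries are
  floored at log(1e-300) to avoid NaNs; the floor only binds on
  zero-support models and moves converged free energies by far less
  than 1e-9 on the shipped fixtures.

The per-sweep free-energy trace is non-increasing (a tested contract).
The approximate complete posterior reuses the exact predictive-factor
machinery with the posterior factor replaced by the mean field.

## Motivations

All motivations are pure functions of (complete posterior, action
sequence).  Design points:

* **Expected free energy** defaults to the per-timestep sum (the common
  convention); the joint-path form is available by configuration.  The
  per-timestep information-gain term is computed by marginalizing the
  sensor-path predictive to each time step independently — whether
  cross-time sensor correlations should be marginalized before or after
  conditioning is ambiguous in the per-timestep convention, and this
  choice is recorded here.  The goal prior defaults to absent (pure
  intrinsic value) but is implemented (per-time sensor distributions,
  KL penalty).
* **Information gain / knowledge seeking** is exact on ensemble-backed
  posteriors (finite discrete joint over sensor paths × parameter
  points).  On the dirichlet backend the parameter posterior is a
  mixture of Dirichlets with no closed-form KL, so the value is a
  seeded Monte Carlo estimate: θ is sampled from the mixture, and the
  sensor predictive given θ mixes the per-component predictives with
  responsibilities p(component|θ) obtained from Dirichlet density
  ratios — this targets I(Ŝ:Θ) rather than I(Ŝ:(Θ, Ê_{t−1})).  The
  estimator is validated against the exact value on matched ensembles
  (within 0.01 nats at 10⁴ samples).  Restricting the gain to a subset
  of parameter blocks is supported on the ensemble backend by merging
  points identical on the counted blocks.
* **Empowerment** treats the m tail-action sequences as one composite
  open-loop channel input alphabet; capacity is computed by
  Blahut–Arimoto from the uniform input distribution, tolerance 1e-10
  on the upper-minus-lower capacity bound, at most 10⁴ iterations
  (non-convergence raises with the remaining gap).
* **Predictive information** uses half horizon k = ⌊(T̂−t+1)/2⌋ by
  default and refuses k = 0.
* The matrix-form expected free energy (state-belief propagation with
  A/B matrices, goal vectors C) is implemented independently and agrees
  with the general functional to 1e-10 on its specialization domain
  (point-mass parameters, per-timestep mode, no information gain).

## Selection and active inference

Softmax normalizes over *full* action sequences and then marginalizes
to the first action (not per-step), with a max shift for overflow
safety.  Argmax ties break lexicographically in the action-space label
order, smallest first, for bit-reproducible runs.  Thompson sampling
draws one (ê_{t−1}, θ) from the posterior factor and acts greedily on
the predictive factor alone; motivations that evaluate the parameter
posterior are rejected at configuration time.  The induced exact action
distribution (posterior-weighted greedy choices) is also available; on
the dirichlet backend that distribution represents each component by
its posterior-mean parameters.

Active inference ships two optimizers for the self-referential
objective F[φ] + KL(r(â|π) ‖ softmax(γ·Q̂(·, φ))), which the theory
states without an algorithm:

* **two_step** (default, deterministic): coordinate-ascent variational
  inference for φ*, then π* = the softmax prior at φ*, attaining
  KL = 0 — the constructive solution.
* **joint_descent**: seeded derivative-free adaptive random search over
  (state-factor logits, θ parameters, π logits) honoring the coupling;
  the accepted-step trace is non-increasing by construction, tolerance
  1e-6, at most 2000 evaluations.

The precision γ is either fixed or given a finite grid with a prior
(default grid {0.5, 1, 2, 4, 8}, flat); the γ-posterior is optimized by
exact coordinate updates (π ← geometric mean of per-γ softmax targets,
ρ(γ) ∝ prior(γ)·exp(−KL(π ‖ q_γ))).  A singleton grid delegates to the
fixed-γ path, so the reduction is bitwise.  Continuous γ priors are out
of scope.

## Synthetic worlds

The fixture family covers the regimes the motivations distinguish: a
deterministic two-state world (`det2`: identity sensor, stay/flip
actions, start at x0), its noisy variant (`noisy2`: sensor flip
probability 0.1), a 1-D grid with slip noise, a T-maze whose cue
location reveals a hidden context, fully random Dirichlet-sampled
dynamics, and a four-model ensemble in which one action is
uninformative and the other separates the worlds at different rates
(flip probability 1 / 0 / 0.7 / 0.3) — the setting where knowledge
seeking visibly beats undirected exploration.  All fixtures are
generated from seeds; nothing is stored.

These worlds are small and fully enumerable by design: they make exact
Bayesian computation, and therefore oracle-grade testing, possible.
What passing tests on them shows is the *correctness* of the inference
and valuation machinery; they say nothing about scalability to large
state spaces (the exact path grows exponentially in t and horizon, as
flagged by the enumeration cap) or about real sensor statistics.

## Study conditions used by the checks

The long-history parameter-recovery check runs a uniformly random
policy in `noisy2` for T = 200 steps, 20 seeds, checkpoints at
t ∈ {25, 50, 100, 200}.  Exact Dirichlet-backend inference enumerates
|Ê|^t trajectories and is infeasible at those horizons, so the
posterior mean of the dynamics block is taken from the mean-field
(CAVI) Dirichlet factors — the approximation this framework itself
prescribes for long histories.  The agent's sensor prior is confident
and correct (concentrations 18/2 per row, matching the known 0.1 flip
noise): the agent knows its sensor and learns the dynamics, which also
pins the latent-label identity that a flat prior leaves symmetric.  The
error metric is the mean over (action, state) rows of the L1 distance
between the posterior-mean transition row and the truth.

The knowledge-seeking comparison runs greedy KSA against a uniform
random agent on the four-model ensemble (T = 15, 50 paired seeds, true
world drawn per seed from the uniform prior) and compares final exact
posterior entropy over the four worlds.

The exact-vs-variational policy-agreement regression uses a two-state
world with uniform start, origin-dependent transitions and
state-dependent sensor ambiguity (rows (0.7, 0.3) and (0, 1)), where
expected free energy genuinely separates actions; greedy choices agree
on ≥ 90% of steps across 20 seeds at t ≤ 4.

Problem sizes throughout (two-state worlds, horizons 1–2, 20–50 seeds)
are chosen so every check is exact or tightly sampled while the whole
suite stays desk-scale.

## Known limitations

Exact inference is exponential in t (dirichlet backend) and in the
horizon (all backends); the cap makes this explicit rather than slow.
Mean-field inference inherits the usual overconfidence and
label-symmetry saddles.  Closed-loop empowerment, policy-space value
functions, hyperparameter (ξ) inference, approximation of the
predictive factor, and continuous state spaces are out of scope.
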