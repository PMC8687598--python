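# Methods

## Model

A reaction network is a continuous-time Markov chain `X(t) ∈ ℕ₀ⁿ` with `K`
channels. Channel `k` consumes `ν_k`, produces `ν′_k`, displaces the state
by `ζ_k = ν′_k − ν_k`, and fires at propensity `λ_k(x)`. Built-in
propensity kinds:

* **mass action** — `λ_k(x) = c_k Π_i C(x_i, ν_ki)` (binomial coefficients
  of the reactant counts; zero on reactant shortage);
* **activating Hill** — `b + k_m x^H / (k_0 + x^H)` of one regulator
  species, used for catalytic production with a basal rate;
* **repressing Hill** — `b + k_m / (k_0 + x^H)`, used for negative
  feedback;
* **custom** — any user callable `(state, params) → rate ≥ 0`.

Rate constants are registered by *name* on the network, and one name may be
shared by several reactions (in the example families, a single `γ` governs
all degradations), so the sensitivity table has exactly one column per
physical constant. Analytic parameter gradients `∂λ_k/∂θ` are implemented
for all built-in kinds; custom kinds fall back to central differences with
step `1e-6·max(1, |θ|)`.

The chain is assumed non-explosive on `[0, T]`. This is a *documented
assumption*, not a checked property; the simulator guards it only with a
configurable cap on jumps per path (default `10⁷`).

## Exact simulation and centred counters

Trajectories are sampled with the modified next reaction method: each
channel owns a unit-rate Poisson clock consuming internal time at rate
`λ_k(X(t))`, and the next firing is the channel whose clock reaches its
next exponential arrival first. This yields the reaction counters `R_k(t)`
directly, and — because propensities are piecewise constant between jumps —
the compensators `∫₀ᵗ λ_k(X(s)) ds` are integrated *exactly* as finite
sums, not by grid quadrature. The centred counters
`R̃_k = R_k − compensator` are therefore exact mean-zero local martingales;
the only discretisation anywhere in the training pipeline is the evaluation
grid of the policy map. Paths are càdlàg and grid restriction samples the
post-jump state. Trajectory `i` of a batch with seed `s` draws from the
dedicated stream seeded by `(s, i)`, so batches are bit-reproducible and
order-independent.

## Loss and training

On the uniform grid `t_j = jT/J` the stochastic integral of the martingale
identity is evaluated by the left-endpoint recursion
`Y_j = Y_{j−1} + V(t_{j−1}, X(t_{j−1})) (R̃(t_j) − R̃(t_{j−1}))`, `Y_0 = Y`,
and the loss is the batch mean of `Σ_i φ((g_i(X(T)) − Y_{J,i})/Δ_i)` with
`φ(x) = x²` for `|x| < 1` and `2|x| − 1` otherwise (continuously
differentiable at the junction; quadratic near zero, L1-like for
outliers). The thresholds `Δ_i = 1 + |mean| + 2·SD` of the training-batch
terminal outputs equalise output scales. An optional sparsity penalty
`μ Σ(|W| + |b|)` is available but off by default (`μ = 0`).

The policy map is a fully connected ReLU network per temporal segment. Its
input is the state (raw copy-numbers by default; affine standardisation
from training-batch statistics is available behind a config flag) together
with `2r` trainable temporal features `exp(a_i(T−t))` and
`sin(w_i(T−t) + ψ_i)` — on a finite state space the backward value function
is a matrix exponential in the remaining horizon, so its time dependence is
spanned by decaying/oscillating modes and the features let the network
learn the dominant ones. One shared feature dictionary feeds the whole
segment. The output layer is linear with `R·K` units (the hidden width
`N_H = 4` cannot carry an `R × K` matrix directly, so the last affine map
widens to the output dimension). For oscillation-prone dynamics the map can
be split into `N_T` structurally identical segment networks over
`[(m−1)T/N_T, mT/N_T)`; segments are independent and no continuity across
boundaries is asserted. Defaults: `L = 2` hidden layers, `N_H = 4`,
`r = 1`, `N_T = 1` (`N_T = 5` preset for the feedback cascade).

Initialisation: weights from the symmetric fan-in-scaled uniform
`U(±√(6/fan_in))`, biases zero, decays `a_i ~ U(−1, 0)` (decaying-mode
prior for the ergodic examples), frequencies `w_i ~ U(0, 1)`, phases zero.
The trained decays are left unconstrained: nothing enforces `a_i ≤ 0`
during training, the prior only sets the starting point.

Optimisation is full-batch adaptive-moment gradient descent (Adam, initial
rate 0.01, decayed ×0.2 at 60% and 85% of the 10,000-iteration budget) over
the policy parameters and the free vector `Y`, which starts at the
training-batch sample mean of the outputs (an unbiased warm start for the
identity `Y = E[g(X(T))]`). Plain constant-rate SGD trains poorly on this
loss; the optimiser and schedule are config-overridable. The training batch
stays fixed for all iterations. Validation loss on an independent batch is
logged every 100 iterations and reported normalised to its first logged
value. Forward evaluation and exact reverse-mode gradients of the entire
objective (through the recursion, the network, and the temporal features)
are hand-written in numpy; they are property-tested against central finite
differences at `1e-4` relative tolerance.

## Sensitivity estimation

With the policy substituted for the jump differences `Δ_k V_g`, the
sensitivity of every output to every registered parameter is the
expectation of a time integral along already-simulated paths, estimated as

    S[i, p] = (1/M) Σ_q trapz_j( Σ_k ∂λ_k/∂θ_p(X^q(t_j)) · V_{i,k}(t_j, X^q(t_j)) )

over the training batch, with per-entry standard errors across paths. The
time quadrature is **trapezoidal** on the trajectory grid rather than the
left-endpoint rule of the loss recursion: the integrand's expectation is
smooth in `t`, and a one-sided rule leaves a deterministic `O(1/J)` bias
(≈ 0.25% at `J = 200`) that dominates the Monte-Carlo error for components
whose per-path integrand is state-independent — e.g. the birth-rate
sensitivity of a birth-death mean, where every path contributes the
identical deterministic sum and the sample variance is zero. The
trapezoidal rule uses exactly the same evaluations and reduces that bias to
`O(1/J²)`; the loss recursion itself keeps its left-endpoint form, which is
what the pathwise identity discretises.

The estimator produces the whole `R × P` table from one batch and one
policy: the number of simulator calls does not depend on `P`.

## Oracles

* **Forward FSP** — the master equation restricted to a box
  `0 ≤ x_i ≤ b_i`, `dp/dt = Qᵀp`, solved by sparse matrix-exponential
  action (sequential `expm_multiply` between query times). The diagonal of
  the truncated rate matrix carries the *full* outflow, so probability
  leaving the box drains out of the system; the leaked mass `1 − Σp` is
  tracked and reported, never silently renormalised — it is the method's
  own error bound. A guard refuses boxes above `2×10⁵` states. Default
  bounds per species: `mean + 10·SD` of a 200-path pre-run (and at least
  the pre-run maximum), since the horizon is short and the examples are
  ergodic.
* **Backward FSP** — `V_g(t) = exp(Q(T−t))g` on the same box, solved once
  globally (not per trajectory), with the jump differences `Δ_k V_g`
  zero-filled where `x + ζ_k` leaves the box. The tabulated differences
  double as an *exact policy* (`TabularPolicy`) for validating the loss
  recursion and the sensitivity estimator independently of training.
  Near the truncation boundary the backward solution deviates from its
  infinite-state counterpart (value escaping the box is lost); comparisons
  against closed forms are therefore made on interior states.
* **Moment ODEs** — for networks whose propensities are affine in the state
  (`λ_k = a_k + b_k·x`; mass action of order ≤ 1), the first and second
  moment equations close exactly and are integrated with fixed-step RK4
  (step `T/2000`), with parameter sensitivities propagated alongside by
  forward-mode differentiation of the same ODEs. Non-affine networks are
  refused (use FSP).
* **Closed forms** — the single-species birth-death process started at zero
  has `X(T) ~ Poisson((k/γ)(1 − e^{−γT}))`; its moments and all their
  parameter derivatives are available in closed form.
* **Monte-Carlo baseline** — sample mean, standard error and 95% CI of the
  terminal outputs over an independent 1000-path batch, as a conventional
  simulation-based reference.
* **Deterministic sensitivity** — the policy-map integral evaluated with
  FSP-exact quantities (trapezoid on 200 uniform time steps; convergence
  verified by doubling in tests), cross-checked against central finite
  differences of the FSP expectation (relative step `1e-4`). Two
  independent oracles for the same quantity.

## What the examples emulate, and what they do not

The four built-in families (independent birth-death; linear cascade;
cascade with activating-Hill catalysis; cascade with repressing-Hill
feedback, all with `2n` reactions, zero initial copies, horizon `T = 1`,
and the constants `k = 10, γ = 1`, `β₀ = 10, k = 5`, `b = 1, k_m = 100,
k_0 = 10, H = 1`) cover linear and nonlinear propensities, feed-forward and
feedback topology, and monotone and oscillation-prone dynamics at low copy
numbers. They are *synthetic* study conditions: real intracellular networks
add features none of the tests exercise — multiscale rate separation,
state-dependent volume or cell division, time-varying inputs, unobserved
species. Passing tests demonstrate correctness of the machinery and
accuracy on these conditions, not performance on such systems.

## Numerical choices and degenerate inputs

* Default protocol sizes: `T = 1`, `J = 50`, `M = 100` training and 100
  validation paths, 10,000 iterations, 1000-path MC baseline.
* Heavy statistical checks run at 10,000 paths; the trained-solver
  accuracy checks train the full 10,000 iterations on `n = 5` (birth-death)
  and `n = 2` (cascades) — sizes at which exact oracles are available to
  compare against while the whole suite stays quick on one CPU.
* Thresholds `Δ` require at least two training paths; non-positive `Δ` is
  rejected. A degenerate all-zero-rate network yields zero counters and a
  zero initial validation loss; the normalised trace is then left
  unnormalised instead of dividing by zero.
* `t = T` closes into the last temporal segment; grid restriction at a
  jump instant takes the post-jump state (càdlàg convention).
* Training aborts with diagnostics if the loss becomes non-finite.
* Reports are JSON plus a flat CSV, every row tagged with the method that
  produced it (`deepcme`, `mc`, `closed_form`, `moment_ode`, `fsp`) and the
  seeds; reruns with the same seed are bit-identical up to timestamps and
  runtimes.

## Open design points

* The Hill exponent `H` is a registered parameter like any other, so its
  sensitivity column is computed and reported; downstream filtering of
  "significant" sensitivities is left to the user, as no principled
  threshold presents itself.
* The training grid is uniform (`t_j = jT/J`); non-uniform grids are out of
  scope.
* Whether the temporal decay rates should be constrained non-positive is
  unresolved; they are initialised negative and left free.

## Known limitations

* FSP is exponential in the species count; for `n ≳ 3` with these copy
  numbers only the Monte-Carlo baseline and closed forms remain as
  references.
* Sensitivity accuracy of the trained solver is limited by how well the
  tiny policy network approximates the jump differences; on the examples
  the moment estimates land within a few percent while sensitivities are
  good to roughly 10–25%, consistent with the estimator's validation under
  the exact policy being far tighter. Enlarging the training batch improves
  this; enlarging the network alone generally does not.
* No τ-leaping, hybrid, multilevel or reduced-model simulation; no
  time-dependent propensities; no SBML import.
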