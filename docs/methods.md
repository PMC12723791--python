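# Methods

## Model

`gatedmem` simulates a continuous-state (graded-response) associative
memory network of Amari–Hopfield type whose neurons are multiplicatively
gated by an auxiliary, activity-driven neuromodulator layer:

    dx_i/dt   = sigma(z_i) [ -x_i + (g/sqrt(PN)) sum_{j != i} J_ij phi(x_j) ]
    tau_z dz_i/dt = -z_i + (1/sqrt(N)) sum_j W_ij phi(x_j)

with `phi(x) = tanh(x)`, Hebbian couplings `J = sum_mu xi^mu (xi^mu)^T`
built from `P` stored patterns (iid binary ±1 by default; Gaussian
supported for universality checks), iid standard normal asymmetric
inter-layer couplings `W`, and the logistic gate
`sigma(z) = 1/(1 + exp(-gamma z))`.  The `1/sqrt(PN)` and `1/sqrt(N)`
normalizations keep both drives O(1) at order-one memory load
`alpha = P/N`.  The interaction sum excludes the autapse (`j != i`);
retaining the diagonal (`J_ii = P`) adds a strong self-excitation
`g sqrt(alpha) phi(x_i)` that pins neurons at their current sign, inflating
the apparent capacity (to ~0.15–0.16 at N=1000) and leaving a spurious
steady overlap (~0.3) in the overload regime; with the autapse excluded the
ungated network reproduces the expected critical capacity of 0.13 at
g = 1.5 and the overload overlap decays toward zero with N.

The gate multiplies the *entire* neuronal drift, so it rescales the
effective integration time-constant: `sigma = 0` freezes a neuron exactly
(bit-exact in the explicit Euler scheme).  `gamma = 0` gives
`sigma ≡ 1/2`, i.e. the standard ungated network under the time rescaling
`t -> t/2`; `gamma = inf` is implemented as an exact step function with
`sigma(0) = 1/2` (the pointwise limit of the logistic family), not as a
large finite slope, to avoid overflow and an arbitrary open/closed choice
on a measure-zero set.

Defaults: `g = 1.5`, `tau_z = 1`, `N = 1000`, explicit Euler with
`dt = 0.2` for network integration, `0.25` for two-pattern flow maps and
`0.02–0.2` for DMFT.  Retrieval is measured by the overlap (Mattis
magnetization) `m_mu = (1/N) sum_i xi_i^mu phi(x_i)`; in the binary gating
limit it decomposes exactly into gate-closed and gate-open sub-population
overlaps, `m = rhoF mF + rhoA mA`.

## Protocols

**Cued initial conditions.** `x(0) = c1 xi + eta` with `eta` iid standard
normal and `c1` found by bisection on the strictly monotone map
`c1 -> (1/N) sum tanh(c1 + xi_i eta_i)` so the realized overlap matches the
target within 1e-3 (noise variance 1, matching the stated z(0)
initialization; this choice affects the retrieval boundary `m_c(alpha)`
quantitatively).  The two-pattern variant solves `(c1, c2)` by damped
Powell-hybrid root finding with the analytic Jacobian.

**Phase diagrams and capacity.** Steady-state overlaps are averaged over
independent quenched-disorder realizations (patterns, W, cue noise, z(0)
all redrawn per realization, each cell seeded deterministically).  The
model never defines "retrieval failure" by a number, so the critical
capacity estimator reports the largest load whose mean steady overlap
exceeds half the retrieval-plateau value (the sweep maximum); near a sharp
transition the estimate is insensitive to this threshold.  The retrieval
boundary `m_c(alpha)` interpolates the same half-maximum level crossing
along the cue axis.  Long runs stop early once `max_i |dx_i|/dt < 1e-7`
(`1e-8`-`1e-9` for fixed-point experiments); the dynamics are
non-chaotic and converge to fixed points, so early stopping changes
steady-state readouts only below these tolerances.

## Dynamical mean-field theory

In the thermodynamic limit the network maps onto a single-site process

    dx/dt = sigma(z) [ -x + (g/sqrt(alpha)) xi m(t)
                       + g sqrt(alpha) ∫_0^t Ktilde(t,u) phi(u) du + eta_x(t) ]
    tau_z dz/dt = -z + eta_z(t)

with `m(t) = <xi phi(t)>`, `<eta_z eta_z'> = C_phi(t,t') = <phi phi'>`, and
`<eta_x eta_x'> = g^2 [K C_phi K^T](t,t')` where `K = delta + Ktilde` and
`Ktilde` is the causal Volterra resolvent of `(g/sqrt(alpha)) R`,
`R(t,t') = d<phi(t)>/dh_x(t')` being the response to a field inside the
gated bracket.  These coefficients follow from a cavity argument under the
`1/sqrt(PN)` scaling: the condensed pattern contributes the coherent drive
`(g/sqrt(alpha)) xi m`; each uncondensed overlap is amplified by the
network's linear response, giving the resolvent both in the retarded drive
(`a * alpha * ∫ K phi`, whose delta part vanishes with the autapse) and in
the noise (`a^2 alpha K C K^T = g^2 K C K^T`).  Equivalently, with the
propagator `G = (g/sqrt(alpha)) (delta + Ktilde)` the noise is
`alpha G C_phi G^T` and the retarded drive `alpha ∫ G phi`; `DMFTState.G`
stores this object with the delta discretized as `1/dt` on the diagonal, so
`cov_x = alpha dt^2 G C_phi G^T` holds to rounding.  A standalone
`update_propagator` integrates the alternative Volterra form
`dG/dt = delta(t-t') + ∫ R G` by forward stepping (unit jump at `t = t'`),
verified against step-kernel and exponential-decay oracles.

**Self-consistency loop.** `solve_dmft` iterates {m, C_phi, R} with
damping (default 0.5; 0.3–0.35 is used for the binary gate, whose step
nonlinearity makes the fixed-point map rougher) over a Monte Carlo
ensemble of M paths.  One set of standard normal draws is fixed up front
and re-colored by the current covariances every iteration (common random
numbers), so the loop converges to the fixed point of a fixed finite-M
estimator instead of chasing sampling noise; covariances are factorized
after a relative diagonal jitter of 1e-10 (eigenvalue clipping as a
fallback).  Initial conditions mirror the many-body cue protocol.

**Response estimation.** Two estimators are provided.  The default uses
the Novikov/Furutsu identity `E[phi(t) eta_x(t')] = ∫ cov_x(t',u) R(t,u) du`,
solved row by row on the causal block with a small ridge (1e-3 relative);
it costs O(M T^2) and is accurate at order-one load.  At small `alpha` the
resolvent multiplies estimator noise by `g/sqrt(alpha)` per kernel
application and exponentiates it, so there `solve_dmft` switches to the
impulse estimator: re-simulate the ensemble with a one-step field impulse
of area eps at each (optionally strided) perturbation time, under common
random numbers, which is a noise-free pathwise derivative up to O(eps).
Both estimators agree within Monte Carlo error on nonlinear noisy test
systems, and the impulse estimator reproduces the exact discrete Green's
function of a linear system.

**Time-asymptotic limit.** Under a stable-fixed-point ansatz the
self-consistency reduces to static scalar equations: active (gate-open)
neurons solve `x = (g/sqrt(alpha)) xi m + B tanh(x) + sqrt(Sigma) w` with
`w` standard normal (Gauss–Hermite quadrature), static kernel closure
`B = g sqrt(alpha) chi_K`, `chi_K = a chi / (1 - a chi)`, noise
`Sigma = g^2 (1 + chi_K)^2 q`, and `chi` the static susceptibility
`<phi'/(1 - B phi')>` of the active sites; the gate-closed population
enters as an imposed overlap `mF` with weight `rhoF` (and self-overlap
`qF`), extracted from binary-gated many-body runs at the extreme cue
overlaps (0.01 and 0.995; an exact unit cue is unreachable under Gaussian
cue noise).  This static closure is a reconstruction validated against
many-body data, not a transcription.  The static equations are bistable in
a narrow `mF` window, so the solved branch shows one genuine fold; branch
continuation (warm-starting from the previous solution) keeps the reported
band single-valued.  The steady-state band `mss_band` evaluates this at the
two extreme `mF` values per load.

## Two-pattern attractor geometry

Flow maps store exactly two exactly-orthogonal ±1 patterns (the second is
the first with N/2 random signs flipped), fix one realization of
(patterns, W, z(0)), and vary only `x(0)` over a grid of target overlaps
covering the diamond `|m1| + |m2| <= 0.9`.  Endpoints are clustered by
single linkage at radius 0.1, chosen to merge within-basin scatter of the
ungated quartet while resolving the four attractors.  Because single
linkage chains, counting the *continuum* of gated fixed points requires the
endpoint spacing to stay comparable to the radius: the quartet-vs-cloud
experiment therefore uses grid spacing 0.2 (41 initial conditions), at
which the gated network yields 6–13 clusters (radius 0.05–0.1) against the
ungated 4 at every radius in 0.05–0.2.  Experiments run in `(m1, m2)`;
`(m+, m-) = (m1 + m2, m1 - m2)` is a reporting transform only.

## Study conditions and problem sizes

All inputs are generated: there is no external data.  The disorder
generator emulates iid binary patterns, iid Gaussian inter-layer couplings
and Gaussian cue noise — it does not emulate structured or learned
neuromodulator couplings, sparse or asymmetric synaptic matrices, spiking
dynamics, or correlated pattern statistics, so passing tests certify the
idealized ensemble only.  Reference experiments use N = 1000 with 20–100
realizations (capacity sweep: alpha in [0.05, 0.25] step 0.01, cue 0.95,
20 realizations; flow maps N = 1000, dt = 0.25, T = 2000).  The test suite
re-runs every phenomenon at reduced sizes chosen for speed — N = 400–500,
10–32 realizations, DMFT at T = 50, dt = 0.2, M = 2000 — with tolerances
set from the corresponding Monte Carlo budgets
(e.g. `3 (1/sqrt(M) + 1/sqrt(n_reps N))` for the DMFT/many-body
comparison); at N = 500 the finite-size capacity estimate lands within one
to two grid steps of 0.13.

## Known limitations

* Finite-size overload runs retain a residual overlap (~0.2 at N = 500,
  ~0.1 at N = 2000) where the infinite system decays to zero; comparisons
  against DMFT are therefore made on transient windows or with budgets
  that account for it.
* The Novikov response estimator degrades at small alpha (see above); the
  impulse estimator is quadratically more expensive in T.
* The time-asymptotic closure treats the static susceptibility as a single
  scalar and imposes closed-population statistics from finite-N runs; its
  band should be read as a validated reconstruction.
* Explicit Euler only, by design; the dynamics are non-stiff and
  non-chaotic at the operating points studied.
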