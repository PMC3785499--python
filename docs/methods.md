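# Methods

## Target density and sampler

The sampler is standard single-site Metropolis–Hastings on the common-log
(log10) parameter scale. The prior is uniform on a box (default: tenfold up
and tenfold down from the reference value of each parameter, i.e. width 2
dex per coordinate). The likelihood is replaced by a product of fitness
measures:

* qualitative: indicators I(C(θ)) of declared bifurcation patterns;
* quantitative: non-negative weights f(z(θ)) of deterministic-simulation
  observables, either raw histogram frequencies or log-normal densities.

Proposals pick one coordinate j uniformly and set θ′_j = θ_j + σ_q(2r − 1)
with r ~ U(0, 1) (or θ_j + σ_q ε, ε ~ N(0, 1) for the normal variant). Both
kernels are symmetric, so the acceptance probability is min(1, w′/w); with
the flat prior inside the box all prior factors cancel. Proposals that leave
the box are rejected outright (no reflection) — the simplest treatment that
preserves detailed balance with a flat prior. Because the chain can never
occupy a zero-weight state, every retained sample satisfies all qualitative
conditions by construction; the test suite re-verifies this on random
subsamples, and checks the stationary law directly against brute-force
normalized targets on tabulated problems.

Evaluation order is qualitative-first: the bifurcation indicators are cheap
relative to a full dynamics run and any zero short-circuits the weight, so
no integration happens for vectors that violate the conditions. The current
weight is cached and replaced only on acceptance; histogram frequencies are
used unnormalized because only weight ratios enter the acceptance
probability.

Initialization is not part of the method's definition, so the package picks
the model's reference vector when it has positive weight and otherwise
rejection-samples the prior (budget 10⁵ draws) — the acceptance ratio is
undefined from a zero-weight state.

Chain defaults for the toy study are σ_q = 0.5, 3.3×10⁵ total steps,
3×10⁴ burn-in, thinning 3 (10⁵ recorded samples). This is a deliberate
tenfold scale-down of a 3.3×10⁶-step design; the recovery and
credibility-ordering results are stable across seeds at this length, which
the replicate runs in `scripts/acceptance.py` demonstrate directly.

## Models and integration

The toy model d[Y]/dt = k_s − k_d[Y] + k_p[Y]⁵/(K⁵ + [Y]⁵) treats the Hill
coefficient n = 5 as a fixed structural constant, not an inferred
parameter. Inference targets (k_d, k_p, K); the input k_s plays the role of
a stimulus level. The two-variable fixture (u′ = input + αv²/(1+v²) − u,
v′ = βu − v) has closed-form fixed points (v = 0 and the roots of
v² − 3v + 1 at α = 3, β = 1) and exercises the multi-dimensional Jacobian
machinery on a system whose answers are known analytically.

Integration is classical fixed-step fourth-order Runge–Kutta, dt = 0.01,
t_end = 100 for the toy model (apoptosis-style settings would use t_end =
500 in minutes). The convergence order measured against the closed form of
the feedback-free linear special case is ≈ 4. Parameters reach the
right-hand side on the linear scale (10^log10 θ); sampling happens on the
log scale.

Noisy simulation ("adding Gaussian noise into the model") is implemented as
an Euler–Maruyama-style additive diffusion: after each deterministic RK4
step every state receives ε√dt with ε ~ N(0, noise_variance), and states
are clamped at zero (concentrations cannot be negative). The √dt scaling is
the only reading under which a stated per-model variance gives
dt-independent trajectory statistics; the rule and variance are recorded in
every trajectory/histogram sidecar. With variance 0 the noisy path is
bitwise identical to the deterministic integrator.

## Steady states, stability and qualitative conditions

Steady states solve rhs = 0. For one-variable models the finder evaluates
the right-hand side on a 4000-point grid over a guaranteed bracket and
refines each strict sign change with Brent's method; exact zeros at grid
points are kept as roots directly (the reference vector produces roots at
exactly y = 0 and y = 0.5, which strict sign products would miss). The
bracket for the toy model is parameter-dependent: every steady state obeys
k_d·y ≤ k_s + k_p, so [0, 1.05·max(5, (k_s + k_p)/k_d)] is exhaustive — a
fixed [0, 5] window would silently lose the high branch for slow
degradation/strong feedback corners of the prior box. For multi-variable
models the finder runs Newton–Raphson (tolerance |rhs| ≤ 1e−10, ≤ 100
iterations, iterates projected onto the search box) from a regular grid of
starting points, deduplicates converged roots (radius 1e−6) and re-verifies
each against the root tolerance.

Stability comes from the eigenvalues of the Jacobian (analytic when the
model provides one, central finite differences otherwise). A maximum real
part within 1e−8 of zero is labelled *marginal*; conditions treat marginal
states as failures because they demand structurally robust counts.

A condition is a named conjunction of clauses, each requiring **exact**
stable/unstable counts at one input level plus optional thresholds on the
lowest/highest stable branch (the form needed for "the low stable branch of
active caspase-3 is below 1 nM"-style statements). The toy study uses
bistability B = {2 stable + 1 unstable at k_s = 0.2; 1 stable at 0.3; 1
stable at 1.0} and irreversibility I = B ∪ {2 stable + 1 unstable at
k_s = 0}.

## Observables and fitness measures

Execution time is the first grid time at which the output reaches 90% of
its maximum; switching time is the time between first crossings of 2.5% and
97.5% of the maximum. First-crossing semantics on the discrete grid are
used without interpolation — at dt = 0.01 the discretization error is below
every tolerance in play, and the results are exactly reproducible.

For deterministic trajectories the maximum is taken over the trajectory
grid; for the monotone dynamics in scope this coincides with the high
stable branch from bifurcation analysis. For **noisy** replicates the two
definitions diverge: the grid maximum of a noisy path is inflated by
extreme-value excursions (at noise variance 0.01 the T_e ensemble mean
shifts from ≈ 2.7 to ≈ 4.8 time units, and the noise-free value ends up in
the far tail of its own histogram). The generator therefore thresholds
noisy replicates against the noise-free trajectory maximum — the
"maximum from dynamics simulation or bifurcation analysis" convention —
so the histograms measure the rise of the underlying signal rather than
noise spikes. `execution_time`/`switching_time` expose this as an optional
`reference_max` argument.

Histogram fitness uses half-open bins [e_i, e_{i+1}) with the last bin
closed; values outside the edges score zero. Log-normal fitness is
parameterized by the natural-scale mean m and SD s via σ² = ln(1 + s²/m²),
μ = ln m − σ²/2 (the settings used for apoptosis-style switching/execution
times are (23, 10) and (15, 3) minutes).

## Synthetic-data generator

The generator emulates population-level experiments: n = 10000 noisy
replicates at the true parameter vector and input k_s = 1.0, observables
T_e and Y_end (= [Y] at t = 100), histogrammed into 50 equal-width bins
spanning the replicate range. It captures measurement-like dispersion via
intrinsic additive noise only; it does not model extrinsic (cell-to-cell
parameter) variability, correlated noise, or detection limits, so passing
recovery tests demonstrate internal consistency of the inference machinery,
not robustness to real experimental error structure.

Recovery experiments default to noise variance 0.01 (the "weak noise"
setting): the sharper histograms make mode recovery unambiguous at the
reduced chain length. Replicates that produce non-finite trajectories are
dropped and counted; more than 1% drops abort generation.

## Posterior summaries

Marginals are histograms over the prior range on the log10 scale, 50 bins
by default (bin width 0.04 dex for the tenfold prior); the mode is the
center of the maximum-probability bin, leftmost on ties. The 95% credible
interval uses nearest-rank empirical 2.5%/97.5% quantiles computed on the
linear scale, reported as log10(upper/lower) so that the full prior box
reads as 2.0. Posterior-predictive observable histograms re-simulate the
deterministic dynamics for a 10⁴-vector uniform subsample of the trace.

## Numerical/engineering choices

The single-variable toy path (integration, steady-state counting, the whole
chain loop, the noisy-ensemble generator) is compiled with numba; the
compiled kernels consume the same `numpy.random.Generator` stream as the
Python code and mirror the generic pure-Python implementations operation
for operation. The test suite asserts bitwise equality of target weights
and of entire short chains between the two routes, so the fast path is an
optimization, never a second definition of the method. All randomness in an
experiment derives from a single user seed (generator and chain streams are
split deterministically), making every pipeline bit-reproducible.

## Known limitations

* Exact-count condition semantics plus grid-resolution root finding mean
  that parameter vectors extremely close to a saddle-node boundary can be
  mis-counted; the marginal-stability band and the dense grid make this a
  measure-zero concern for sampling, but continuation-quality branch
  tracking is out of scope.
* The sampler is a single chain with fixed σ_q; no adaptation, tempering or
  population variants.
* Credible intervals are central quantile intervals, not HPD intervals.
* Fixed-step RK4 is appropriate for the non-stiff models in scope; stiff
  systems would need a different integrator.
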