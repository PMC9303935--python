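# Methods

## Model and proposal family

All samplers are Metropolis–Hastings chains targeting an unnormalized
density π on R^d with acceptance probability
α(x,y) = min{1, π(y)q(y,x) / (π(x)q(x,y))}.

A *first-order locally balanced* proposal tilts a symmetric noise kernel
μ_σ by a balancing function g:(0,∞)→(0,∞) obeying g(t) = t·g(1/t):

    Q^(g)(x,dy) = Z(x)^{-1} g(e^{∇log π(x)·(y−x)}) μ_σ(y−x) dy,
    Z(x) = ∫ g(e^{∇log π(x)·z}) μ_σ(z) dz.

The balancing identity is exactly the condition under which Q^(g) is
π-reversible for log-linear π; it is also the functional equation
satisfied by MH acceptance rules, which is where the admissible g come
from. Two members matter here:

- g(t) = √t gives Z = e^{a²σ²/8} (Gaussian moment generating function,
  a = ∇log π(x)) and Q^(g) equal to the Langevin proposal
  N(x + σ²a/2, σ²) *exactly* — completing the square in the exponent.
  This closed form is the package's strongest correctness oracle: the
  generic quadrature/normalizer path must reproduce it to 1e-10.
- g(t) = t/(1+t) (the Barker rule) gives Z = 1/2 for *any* a and any
  symmetric μ_σ, because g(e^{az}) + g(e^{-az}) = 1. The resulting
  kernel 2μ_σ(z)/(1+e^{-az}) is skew-symmetric (symmetric density times a
  logistic CDF factor) and is sampled exactly by the sign-flip rule:
  z ~ μ_σ, keep the sign with probability 1/(1+e^{-az}).

In d dimensions the Barker proposal is applied coordinate-wise
(independent z_i and sign decisions driven by ∂_i log π(x)); the
alternative that flips *all* coordinates with a single global decision is
implemented for comparison, since its spectral gap provably cannot beat
twice the random walk's — a bound the grid oracle verifies numerically.

The MH log-ratio for the Barker kernel reduces to

    log π(y) − log π(x) + Σ_i [ log(1+e^{−z_i g_{x,i}}) − log(1+e^{z_i g_{y,i}}) ]

with z = y − x; every logistic/softplus term is evaluated through
log1p(e^{−|u|}) + max(u,0) because |z·g| reaches ~1e4 on the stiff
scenario targets. The ratio is cross-checked in tests against the generic
two-sided density computation at 1e-10.

## Why this buys robustness

Efficiency and fragility are both quantified by the spectral gap of the
chain as the target's scale in one coordinate is multiplied by λ
(π^(λ)(x) = λ^{-1}π(x₁/λ, x₂, …) with the proposal held fixed). For the
random walk the gap decays as Θ(λ); for MALA it decays exponentially in
1/λ because the drift σ²∇log π/2 grows without bound; the Barker kernel,
whose gradient enters only through a bounded logistic weight, retains the
Θ(λ) decay while keeping an O(σ³) per-coordinate acceptance expansion —
the same order as MALA, hence the same d^{1/3}-type dimension scaling.
The package verifies the finite-grid versions of these statements
numerically (log–log slope of gap against λ, acceptance-scaling slopes,
total-variation collapse onto the random-walk kernel at rate 1/λ) rather
than asserting any asymptotic theorem as a limit.

## Adaptive tuning

The global scale and a diagonal pre-conditioner are tuned by stochastic
approximation with learning rate γ_t = t^{-κ}:

    log σ_t = log σ_{t−1} + γ_t (α(X_t, Y_t) − α*)
    μ_t     = μ_{t−1} + γ_t (X_t − μ_{t−1})
    Σ_t,ii  = Σ_{t−1},ii + γ_t ((X_t,i − μ_{t−1},i)² − Σ_{t−1},ii)

Defaults: κ = 0.6 (smaller is unstable for MALA, larger adapts slowly),
target rates α* = 0.23 (RWM), 0.57 (MALA), 0.40 (Barker); σ₀² = 2.4²/d
for RWM and 2.4²/d^{1/3} for MALA, inherited by Barker and HMC
(optimal-scaling starting points); Σ₀ = I; chains start iid N(0, 10²)
unless a posterior supplies prior draws. The acceptance innovation is the
Rao-Blackwellised probability α(X_t, Y_t), not the accept indicator (the
two were compared and adapt indistinguishably; the probability has lower
variance). The covariance innovation deviates from the *previous* running
mean: with the updated mean the first update (γ₁ = 1) annihilates the
deviation and Σ collapses onto its floor, stalling the early transient —
measured on the stiff scenario this triples the adaptation time.
Σ_t is floored at 1e-12 so a stalled chain can never zero out a proposal
scale; off-diagonals are identically zero (learning a dense
pre-conditioner is out of scope). The per-coordinate proposal scale is
σ_t √Σ_t,ii, applied inside the noise draw and the sign-flip probability
alike.

Tuning convergence is tracked by
d_t = (E[(1/d) Σ_i (log Σ_t,ii − log Σ_ii)²])^{1/2}, the root of the
across-run expected mean-square log-error against the target's true
diagonal covariance; τ_adapt(ε) is its first passage below ε = 1. The
expectation placement admits two readings; the root-mean-square reading
is the default and the mean-of-roots variant is available
(`aggregate='mean'`). The two differ only in how straggler runs are
weighted (RMS is slightly more conservative). τ_adapt is a first-passage
time of a slowly decaying noisy curve and is strongly right-skewed across
replications: at the default 10-repetition protocol on scenario 1 its
replication distribution spans roughly 480–900 around a median near 560.
Quantitative comparisons should treat it accordingly.

## Targets and synthetic data

- Scenario 1: independent Gaussians with sd (0.01, 1, …, 1) — one stiff
  coordinate, the λ-framework made concrete.
- Scenarios 2–4 draw per-coordinate scales log η_i ~ N(0,1) once, under a
  recorded seed, so that the true Σ used by d_t refers to the same target
  instance across repetitions. Scenario 3 uses hyperbolic coordinates
  −(ε + (x_i/η_i)²)^{1/2} with ε = 0.1 (smoothed Laplace; variance by 1-d
  quadrature, no closed form); scenario 4 uses skew-normal coordinates
  with shape α = 4 (mean ηδ√(2/π), variance η²(1 − 2δ²/π), δ = α/√(1+α²)),
  whose log-CDF factor is evaluated through log_ndtr and the stable ratio
  φ/Φ = exp(log φ − log Φ) so gradients survive arguments below −8.
- The Poisson random-effects model: y_ij | η_i ~ Poisson(e^{η_i})
  (i = 1..50 groups, j = 1..5), η_i | μ ~ N(μ, σ_η²), μ ~ N(0, 10²), with
  σ_η known. The posterior over (μ, η) has 51 dimensions, light tails and
  gradients up to ~n·e^η, which is precisely the regime where unbounded
  drifts destabilize. The generator draws η* from the prior around μ* and
  rejects parameter settings whose rates overflow. Benchmark settings:
  (μ* = 5, σ_η = 1) and (μ* = 10, σ_η = 3); the harder setting produces
  counts near 10⁸, heterogeneous across groups.

What the synthetic targets do *not* emulate: correlated coordinates
(pre-conditioning is diagonal by design), multimodality, and discrete or
constrained parameters. Passing benchmarks here demonstrates robustness to
scale heterogeneity and tail stiffness, not to those features.

## Diagnostics

ESJD uses the Rao-Blackwellised estimator mean_t[α_t‖Y_t − X_{t−1}‖²],
which shares its expectation with the naive squared-displacement mean but
has lower variance. ESS is T·Var(x)/S(0) with the zero-frequency spectral
density from a Yule-Walker AR fit whose order (≤ 10·log₁₀T) minimizes
AIC — the estimator family used by the standard MCMC diagnostic tools; it
is validated against the closed-form AR(1) integrated autocorrelation time
and an independent ESS implementation at 10%. Step-size optimization runs
one stationary-start chain per σ grid point (exact target samplers exist
for all built-in targets; the hyperbolic families use inverse-CDF
sampling on an adaptively widened grid), all grid points advancing in one
vectorized batch.

## Spectral oracles

MH kernels with closed-form proposal densities (RWM, MALA, Barker,
global-flip) are discretized on regular grids — 400 points in 1-d over
±8 sd of each λ's target, 80 per axis in 2-d — with off-diagonal entries
q·α·Δ and the rejection mass absorbed exactly on the diagonal; rows are
checked stochastic, the chain reversible, and edge cells must hold less
than 1e-8 of the mass. The gap is 1 − λ₂ of the π-symmetrized matrix
(dense eigensolve up to 1200 states, Lanczos above); on small random
reversible chains it is cross-checked against direct numerical
minimization of the Dirichlet form. Gaps below 1e-13 are truncated and
flagged (eigensolver noise floor); doubling the grid moves reported gaps
by under 2%. HMC is excluded from the grid oracle — its proposal density
is not a closed-form kernel — and is covered indirectly through the L = 1
equivalence with MALA.

The total-variation collapse oracle evaluates
TV(Q_λ(x,·), Q^R(x,·)) by quadrature as λ grows. Note a degeneracy: the
Θ(1/λ) rate requires (log π)′(0) ≠ 0; for a centred Gaussian base the
leading term cancels and the decay is 1/λ². The shipped checks therefore
use a mean-shifted Gaussian base, where the generic rate is visible.

## Numerical choices and edge cases

- Softplus/logistic always through the stable branch; gradients of ±∞
  saturate the flip probability to {0,1} without overflow.
- Ties u = p in the sign draw resolve to b = +1 (probability-zero event,
  fixed for determinism).
- Normalizer quadrature: adaptive, absolute tolerance ~1e-13, integration
  split at the kink z = 0 and extended to ±40σ for unbounded g.
- A proposal with non-finite log-density is rejected with α = 0; a
  rejection returns the cached (x, log π, ∇log π) unchanged, so each
  iteration costs exactly one fresh density-plus-gradient evaluation.
- Fixed-L HMC on a Gaussian resonates when σL is near the half-period
  (e.g. σ = 1, L = 3: the leapfrog map is exactly (x,ξ) → −(x,ξ), every
  proposal accepted, the chain a deterministic flip). This is a property
  of the integrator, not a defect; invariance tests avoid resonant
  settings. With L fixed, the leapfrog energy error decays as σ³.
- All experiment runners are pure functions of their configuration
  (seeds included); chains advance in vectorized batches over repetitions
  and grid points, which is what keeps the full benchmark suite under a
  minute on one CPU.

## Problem sizes

Default protocols: ESJD sweeps use 10⁴ Monte-Carlo samples per σ over
25-point grids spanning 2.5 decades, dimensions {5, 10, 20, 50, 100};
scenario adaptation uses 100 dimensions, 10 repetitions, horizons of
5×10³–2×10⁴ iterations (checkpoints up to 4×10⁴ supported); the Poisson
benchmark runs 5×10⁴ iterations × 10 repetitions with the first half
discarded. The repetition count for the d_t expectation is a configuration
knob (default 10).

## Known limitations

- Only diagonal pre-conditioning; no dense covariance adaptation, no NUTS
  or dynamic trajectory lengths, no tamed/truncated MALA variants.
- The generic-g sampler is one-dimensional (analysis aid); only the Barker
  g has the exact d-dimensional sign-flip sampler.
- MALA's adaptation time on the stiff scenario is reproducible in order of
  magnitude but sits ~25% below its reference value across every protocol
  variant we tested; RWM and Barker reproduce theirs to a few percent
  under the identical harness. The statistic is a first-
  passage time of the most unstable sampler's transient and should be read
  with that variance in mind.
- No real-data readers and no normalizing-constant estimation; all
  log-densities are unnormalized throughout and no diagnostic relies on a
  normalizing constant.
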