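# barkermcmc

Robust gradient-based Markov chain Monte Carlo built around the **Barker
proposal**, with random-walk Metropolis (RWM), Metropolis-adjusted Langevin
(MALA) and fixed-`L` Hamiltonian baselines, Robbins–Monro adaptive tuning,
spectral-gap robustness oracles, and the simulation benchmarks that motivate
the method (heterogeneous-scale targets and a Bayesian Poisson
random-effects posterior).

## The problem

Gradient-based MH proposals (MALA, HMC) mix far better than the random walk
as dimension grows — `Θ(d^{1/3})` or `Θ(d^{1/4})` iterations per effective
sample instead of `Θ(d)` — but they are fragile: if the step size σ is too
large for even one direction of the target, their spectral gap collapses
*exponentially* in the mismatch, whereas the random walk degrades only
polynomially. In adaptive MCMC this fragility is costly, because the
sampler has to mix in order to learn its own tuning parameters.

The Barker proposal keeps the gradient information while restoring the
random walk's robustness. It is the member of the family of **first-order
locally balanced proposals**

    Q^(g)(x, dy) ∝ g(e^{∇log π(x)·(y−x)}) μ_σ(y − x) dy,
    g(t) = t·g(1/t),

with balancing function `g(t) = t/(1+t)` (Barker's classical accept rule).
For this `g` the normalizer is exactly 1/2 and sampling is trivial: per
coordinate draw `z_i ~ N(0, σ_i²)`, keep the sign with probability
`1/(1+exp(−z_i ∂_i log π(x)))`, otherwise flip it, and propose
`y_i = x_i + b_i z_i`. The gradient steers the *direction* of each
increment but never its magnitude, so enormous gradients cannot fling the
chain into regions of near-certain rejection. The choice `g(t) = √t`
recovers MALA exactly, which makes the Langevin kernel a closed-form oracle
for the whole machinery.

The package provides:

- `targets` — iid product targets (Gaussian, hyperbolic, exponential-power),
  the λ-scale family `π^(λ,k)`, four heterogeneous 100-dimensional
  scenarios, and the Poisson random-effects posterior with its synthetic
  data generator;
- `proposals` — Barker, RWM, MALA, fixed-`L` HMC and the global-flip Barker
  variant behind a single `mh_step`, all vectorized over batches of chains;
- `locally_balanced` — balancing-function contract, numeric normalizers
  `Z(x)`, densities, a generic 1-d sampler, and the `O(σ³)` acceptance-
  scaling analysis;
- `adaptation` — Robbins–Monro tuning of the global scale and the diagonal
  pre-conditioner (`γ_t = t^{-κ}`, target rates 0.23/0.57/0.40);
- `diagnostics` — Rao-Blackwellised ESJD, autoregressive-spectral effective
  sample size, the tuning distance `d_t`, `τ_adapt`, burn-in MSE, and
  step-size grid search;
- `spectral` — discretized kernels, spectral gaps, λ-sweeps, the factor-two
  global-flip bound and the `O(1/λ)` total-variation collapse;
- `experiments` / a `barkermcmc` CLI — seeded, configuration-driven runners
  emitting tab-separated tables.

## Worked example

Step-size robustness on a one-dimensional Gaussian (ESJD against σ,
10⁴ Monte-Carlo samples per grid point):

```python
from barkermcmc.experiments import RunConfig, run_esjd_sweep

cfg = RunConfig(experiment="esjd_sweep", target_kind="gaussian", dim=1,
                samplers=("rwm", "mala", "barker"),
                sigma_points=13, mc_samples=10_000, seed=1)
df = run_esjd_sweep(cfg)
print(df.pivot(index="sigma", columns="sampler", values="esjd").round(4))
```

```
sampler     barker    mala     rwm
sigma
0.100000    0.0099  0.0102  0.0094
0.464159    0.2012  0.2177  0.1513
1.000000    0.7280  1.0853  0.4497
2.154435    1.3277  1.2128  0.7197
4.641589    1.1129  0.0278  0.5924
10.000000   0.6426  0.0000  0.3223
100.000000  0.0643  0.0000  0.0379
```

Below the optimum all three samplers coincide; past it MALA's efficiency
vanishes almost immediately (0.028 at σ ≈ 4.6) while Barker and RWM decay
slowly — the robustness-to-tuning contrast in one table.

Adaptive tuning on the stiff scenario (100-dimensional Gaussian, first
coordinate sd 0.01, κ = 0.6, ten repetitions):

```sh
barkermcmc scenario-adapt --scenario 1 --iters 5000 --reps 10 \
    --samplers barker,mala --seed 1
```

```
    experiment  scenario sampler  reps  iterations tau_adapt  accept_rate_tail
scenario_adapt         1  barker    10        5000       897          0.398928
scenario_adapt         1    mala    10        5000     >5000          0.576826
```

`tau_adapt` is the first iteration at which the across-run tuning distance
`d_t` (root-mean-square log-error of the adapted diagonal covariance)
drops below 1: Barker's pre-conditioner stabilizes within a few hundred
iterations while MALA's has not stabilized within this 5000-iteration run;
both chains sit on their target acceptance rates (0.40 / 0.57).

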