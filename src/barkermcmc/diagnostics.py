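"""Performance and convergence metrics.

Rao-Blackwellised expected squared jump distance (ESJD), autoregressive-
spectral effective sample size (the estimator behind coda's effectiveSize),
the tuning-distance d_t between the adapted and true diagonal covariances,
its first-passage time tau_adapt, burn-in mean squared errors of
first-moment estimators, and ESJD-maximizing step-size grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.random import Generator

from .proposals import ProposalScales
from .runner import RunRecord, run_chain
from .targets import TargetDensity
from ._util import rng_from

__all__ = [
    "RunRecord",
    "esjd",
    "ess",
    "dt_metric",
    "dt_curve",
    "tau_adapt",
    "mse_first_moments",
    "optimal_sigma",
    "SigmaSweep",
]


def esjd(run: RunRecord, per_coordinate: bool = False) -> float:
    """Rao-Blackwellised ESJD: mean over t of alpha_t * ||Y_t - X_{t-1}||^2.

    Uses the proposed point and acceptance probability at every iteration,
    which estimates the same stationary expectation as the naive mean of
    ||X_{t+1} - X_t||^2 with lower variance.  ``per_coordinate`` divides by
    the dimension.
    """
    if run.chain.shape[0] < 2:
        raise ValueError("need at least 2 iterations")
    # jump at step t is measured from the pre-step position chain[t-1];
    # t = 0 is dropped since the initial state is not stored.
    jumps = np.sum((run.proposals[1:] - run.chain[:-1]) ** 2, axis=-1)
    val = float(np.mean(run.accept_probs[1:] * jumps))
    if per_coordinate:
        val /= run.chain.shape[-1]
    return val


def _ar_spectrum0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Yule-Walker AR fit with
    AIC-selected order (order <= 10 log10 T), as in coda's spectrum0.ar."""
    T = x.size
    x = x - x.mean()
    v0 = float(np.dot(x, x)) / T
    if v0 == 0:
        return 0.0
    kmax = min(T - 1, int(10 * np.log10(T)))
    # autocovariances up to kmax via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: kmax + 1] / T
    # Levinson-Durbin: sigma2 and coefficients for every order
    sigma2 = acov[0]
    phi = np.zeros(kmax + 1)
    best_aic = T * np.log(sigma2)
    best = (0, sigma2, phi[:0].copy())
    phis = np.zeros(0)
    for k in range(1, kmax + 1):
        if sigma2 <= 0:
            break
        rc = (acov[k] - np.dot(phis, acov[k - 1 : 0 : -1])) / sigma2
        new = np.empty(k)
        new[: k - 1] = phis - rc * phis[::-1]
        new[k - 1] = rc
        phis = new
        sigma2 = sigma2 * (1.0 - rc**2)
        aic = T * np.log(max(sigma2, 1e-300)) + 2.0 * k
        if aic < best_aic:
            best_aic = aic
            best = (k, sigma2, phis.copy())
    _, s2, coef = best
    denom = (1.0 - np.sum(coef)) ** 2
    if denom <= 0:
        return np.inf
    return float(s2 / denom)


def ess(series: np.ndarray) -> float:
    """Effective sample size T * Var(x) / spec0 with an AR-spectral spec0.

    A zero-variance series has ESS 0 by convention (with a warning).
    """
    x = np.asarray(series, float).ravel()
    T = x.size
    if T < 10:
        raise ValueError("need at least 10 samples")
    v = float(np.var(x, ddof=1))
    if v == 0:
        warnings.warn("zero-variance series: ESS defined as 0", stacklevel=2)
        return 0.0
    s0 = _ar_spectrum0(x)
    if s0 == 0 or not np.isfinite(s0):
        return 0.0
    return float(T * v / s0)


def dt_metric(var_diag_t: np.ndarray, true_var: np.ndarray, aggregate: str = "rms") -> float:
    """Tuning distance at one time point:

    d_t = ( E_runs [ (1/d) sum_i (log Sigma_t,ii - log Sigma_ii)^2 ] )^(1/2),

    the root of the across-run expectation of the mean-square log-error
    (``aggregate='rms'``).  ``aggregate='mean'`` instead averages the
    per-run roots; the two coincide for a single run and differ only in how
    straggler runs are weighted.  ``var_diag_t`` has shape (d,) or (R, d);
    the metric is invariant to a common rescaling of both arguments.
    """
    v = np.atleast_2d(np.asarray(var_diag_t, float))
    tv = np.asarray(true_var, float)
    if np.any(v <= 0) or np.any(tv <= 0):
        raise ValueError("variance entries must be positive")
    msq = np.mean((np.log(v) - np.log(tv)) ** 2, axis=-1)
    if aggregate == "rms":
        return float(np.sqrt(np.mean(msq)))
    if aggregate == "mean":
        return float(np.mean(np.sqrt(msq)))
    raise ValueError("aggregate must be 'rms' or 'mean'")


def dt_curve(log_var_trace: np.ndarray, true_var: np.ndarray, aggregate: str = "rms") -> np.ndarray:
    """d_t for every iteration from a (T, R, d) log-variance trace."""
    lt = np.log(np.asarray(true_var, float))
    msq = np.mean((np.asarray(log_var_trace, float) - lt) ** 2, axis=-1)  # (T, R)
    if aggregate == "rms":
        return np.sqrt(np.mean(msq, axis=-1))
    if aggregate == "mean":
        return np.mean(np.sqrt(msq), axis=-1)
    raise ValueError("aggregate must be 'rms' or 'mean'")


def tau_adapt(d_series: Sequence[float], epsilon: float = 1.0):
    """First index t (1-based) with d_t <= epsilon; the string sentinel
    '>T' when the threshold is never attained within the run."""
    d = np.asarray(d_series, float)
    if d.size == 0:
        raise ValueError("empty d_t series")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    hits = np.nonzero(d <= epsilon)[0]
    if hits.size == 0:
        return f">{d.size}"
    return int(hits[0]) + 1


def mse_first_moments(
    chains: np.ndarray,
    target: TargetDensity,
    eta: np.ndarray,
    t: int,
) -> float:
    """Average MSE of first-moment estimators of h_i(x) = x_i / eta_i.

    Uses iterations floor(t/2)+1 .. t (first half discarded as burn-in),
    averages the squared error against the known standardized means over
    coordinates and runs.  ``chains`` has shape (T, R, d) or (T, d).
    """
    if target.true_mean is None:
        raise ValueError("target provides no true means")
    if t < 2:
        raise ValueError("t must be >= 2")
    c = np.asarray(chains, float)
    if c.ndim == 2:
        c = c[:, None, :]
    burn = t // 2
    seg = c[burn:t]  # (t - burn, R, d)
    eta = np.asarray(eta, float)
    h_hat = seg.mean(axis=0) / eta  # (R, d)
    h_true = target.true_mean / eta
    return float(np.mean((h_hat - h_true) ** 2))


@dataclass
class SigmaSweep:
    sigmas: np.ndarray
    esjd: np.ndarray
    best_sigma: float
    best_esjd: float
    at_endpoint: bool


def optimal_sigma(
    kind: str,
    target: TargetDensity,
    sigma_grid: np.ndarray,
    iters: int,
    rng: Generator | int,
    L: Optional[int] = None,
) -> SigmaSweep:
    """Grid search for the ESJD-maximizing global step size.

    One stationary-start chain per grid point (all advanced in a single
    vectorized batch); requires the target to provide an exact sampler.
    The full (sigma, ESJD) curve is returned, and an optimum at a grid
    endpoint is flagged.
    """
    sigma_grid = np.asarray(sigma_grid, float)
    if sigma_grid.max() / sigma_grid.min() < 100:
        raise ValueError("sigma_grid should span at least 2 decades")
    if target.sample is None:
        raise ValueError("stationary-start sweep needs an exact target sampler")
    rng = rng_from(rng, 11) if isinstance(rng, int) else rng
    G = sigma_grid.size
    x0 = target.sample(rng, (G,))
    scales = ProposalScales(sigma=sigma_grid)
    from .proposals import make_state, mh_step

    state = make_state(target, x0)
    total = np.zeros(G)
    for _ in range(int(iters)):
        x_prev = state.x
        state, out = mh_step(state, kind, scales, rng, target, L=L)
        total += out.accept_prob * np.sum((out.y.x - x_prev) ** 2, axis=-1)
    vals = total / float(iters)
    best = int(np.argmax(vals))
    return SigmaSweep(
        sigmas=sigma_grid,
        esjd=vals,
        best_sigma=float(sigma_grid[best]),
        best_esjd=float(vals[best]),
        at_endpoint=best in (0, G - 1),
    )
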