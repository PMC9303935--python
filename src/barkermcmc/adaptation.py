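"""Robbins-Monro adaptive tuning of the global proposal scale and the
diagonal pre-conditioner.

At iteration t (learning rate gamma_t = t^-kappa, kappa in (0.5, 1)):

    log sigma_t = log sigma_{t-1} + gamma_t (alpha(X_t, Y_t) - alpha*)
    mu_t        = mu_{t-1} + gamma_t (X_t - mu_{t-1})
    Sigma_t,ii  = Sigma_{t-1},ii + gamma_t ((X_t,i - mu_{t-1},i)^2 - Sigma_{t-1},ii)

The acceptance innovation is the Rao-Blackwellised acceptance probability,
not the accept indicator; the covariance innovation uses the deviation from
the *previous* running mean (the Andrieu-Thoms stochastic-approximation
recursion: with the already-updated mean the first iteration, where
gamma_1 = 1, collapses Sigma to the floor and the early transient stalls);
off-diagonals are identically zero.  Target rates alpha* are
0.23 (RWM), 0.57 (MALA) and 0.40 (Barker); starting scales follow the
optimal-scaling convention sigma_0^2 = 2.4^2/d for RWM and 2.4^2/d^(1/3)
for MALA, which Barker (and HMC) inherit.

All fields are batched over a leading repetition axis, so R chains adapt
independently in lock step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AdaptState",
    "learning_rate",
    "adapt_update",
    "initial_scales",
    "target_rate",
    "effective_scales",
    "init_adapt_state",
]

_TARGET_RATES = {"rwm": 0.23, "mala": 0.57, "barker": 0.40, "hmc": 0.57}


@dataclass
class AdaptState:
    t: int
    log_sigma: np.ndarray  # (...,)
    mean: np.ndarray  # (..., d)
    var_diag: np.ndarray  # (..., d) diagonal of Sigma_t
    kappa: float = 0.6
    target_rate: float = 0.40
    var_floor: float = 1e-12


def learning_rate(t: int, kappa: float) -> float:
    """gamma_t = t^-kappa; kappa in (0.5, 1) gives diminishing adaptation."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if not 0.5 < kappa < 1.0:
        if kappa in (0.5, 1.0):
            warnings.warn("kappa at the boundary of (0.5, 1)", stacklevel=2)
        else:
            raise ValueError("kappa must lie in (0.5, 1)")
    return float(t) ** (-kappa)


def target_rate(kind: str) -> float:
    try:
        return _TARGET_RATES[kind]
    except KeyError:
        raise ValueError(f"unknown sampler kind: {kind!r}") from None


def initial_scales(kind: str, d: int) -> float:
    """Starting global scale sigma_0 (not squared): 2.4/sqrt(d) for RWM,
    2.4/d^(1/6) for MALA, which Barker and HMC share."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if kind == "rwm":
        return 2.4 / np.sqrt(d)
    if kind in ("mala", "barker", "hmc"):
        return 2.4 / d ** (1.0 / 6.0)
    raise ValueError(f"unknown sampler kind: {kind!r}")


def init_adapt_state(kind: str, d: int, batch: tuple = (), kappa: float = 0.6) -> AdaptState:
    """Fresh adaptation state: sigma_0 by the optimal-scaling rule, mu_0 = 0,
    Sigma_0 = I."""
    return AdaptState(
        t=0,
        log_sigma=np.full(batch, np.log(initial_scales(kind, d))),
        mean=np.zeros((*batch, d)),
        var_diag=np.ones((*batch, d)),
        kappa=kappa,
        target_rate=target_rate(kind),
    )


def adapt_update(astate: AdaptState, x_t: np.ndarray, accept_prob) -> AdaptState:
    """Advance the three Robbins-Monro recursions by one iteration."""
    accept_prob = np.asarray(accept_prob, float)
    if np.any(accept_prob < 0) or np.any(accept_prob > 1):
        raise ValueError("accept_prob must lie in [0, 1]")
    t = astate.t + 1
    g = learning_rate(t, astate.kappa)
    log_sigma = astate.log_sigma + g * (accept_prob - astate.target_rate)
    dev = np.asarray(x_t, float) - astate.mean
    mean = astate.mean + g * dev
    var = np.maximum(astate.var_diag + g * (dev**2 - astate.var_diag), astate.var_floor)
    return replace(astate, t=t, log_sigma=log_sigma, mean=mean, var_diag=var)


def effective_scales(astate: AdaptState) -> np.ndarray:
    """Per-coordinate proposal scale e^{log sigma_t} sqrt(Sigma_t,ii)."""
    return np.exp(astate.log_sigma)[..., None] * np.sqrt(
        np.maximum(astate.var_diag, astate.var_floor)
    )
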