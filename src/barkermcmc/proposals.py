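"""Proposal mechanisms and the Metropolis-Hastings step.

Implements the Barker proposal (coordinate-wise skew-symmetric candidate
kernel built from the balancing function g(t) = t/(1+t)), the random-walk
Metropolis, MALA and fixed-L Hamiltonian baselines, and the global-flip
variant of the Barker scheme.  Every sampler shares one ``mh_step`` entry
point that returns both the new state and the proposal outcome (including
the Rao-Blackwellised acceptance probability used by adaptation and ESJD).

States are batched: ``x`` may have shape ``(d,)`` or ``(R, d)`` for R
simultaneously advancing chains; all kernels vectorize over the leading
axis and accept/reject each chain independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.random import Generator
from scipy.special import expit

from ._util import log_normal_pdf, softplus
from .targets import TargetDensity

__all__ = [
    "ChainState",
    "ProposalScales",
    "ProposalOutcome",
    "make_state",
    "barker_flip_prob",
    "barker_propose",
    "barker_log_density",
    "mh_log_ratio_barker",
    "rwm_propose",
    "mala_propose",
    "mala_log_density",
    "hmc_propose",
    "global_flip_propose",
    "mh_step",
    "SAMPLER_KINDS",
]

SAMPLER_KINDS = ("barker", "rwm", "mala", "hmc", "global_flip")


@dataclass
class ChainState:
    """Current position with cached log-density and gradient.

    The cache means each MH step costs exactly one fresh density-plus-
    gradient evaluation (at the proposed point), matching the per-iteration
    cost of MALA.
    """

    x: np.ndarray
    logpi: np.ndarray
    grad: np.ndarray


@dataclass
class ProposalScales:
    """Per-coordinate proposal scales: effective scale_i = sigma * coord_scale_i.

    The noise kernel mu_sigma is Gaussian; the interface admits other
    symmetric kernels but none ship.
    """

    sigma: float | np.ndarray
    coord_scale: float | np.ndarray = 1.0
    noise: str = "gaussian"

    def effective(self) -> np.ndarray:
        s = np.asarray(self.sigma, float)[..., None] * np.asarray(self.coord_scale, float)
        if np.any(s <= 0):
            raise ValueError("effective proposal scales must be positive")
        return s


@dataclass
class ProposalOutcome:
    y: ChainState
    log_mh_ratio: np.ndarray
    accept_prob: np.ndarray
    accepted: np.ndarray


def make_state(target: TargetDensity, x: np.ndarray) -> ChainState:
    x = np.asarray(x, float)
    return ChainState(x=x, logpi=target.log_density(x), grad=target.grad_log_density(x))


# ---------------------------------------------------------------------------
# Barker proposal


def barker_flip_prob(z, g):
    """p(x,z) = 1 / (1 + exp(-z * grad)): probability of keeping the sign of z.

    Evaluated through the logistic sigmoid, which saturates to 0/1 at
    extreme arguments without overflow.  At grad = 0 this is 1/2 and the
    proposal reduces to the symmetric random walk.
    """
    return expit(np.asarray(z, float) * np.asarray(g, float))


def barker_propose(state: ChainState, scales: ProposalScales, rng: Generator) -> np.ndarray:
    """Draw y coordinate-wise: z_i ~ N(0, (sigma s_i)^2), keep the sign with
    probability 1/(1+e^{-z_i grad_i}), else flip it; y_i = x_i + b_i z_i."""
    s = scales.effective()
    z = s * rng.standard_normal(state.x.shape)
    p = barker_flip_prob(z, state.grad)
    b = np.where(rng.uniform(size=z.shape) <= p, 1.0, -1.0)
    return state.x + b * z


def barker_log_density(x, grad_x, y, scales: ProposalScales):
    """log Q^B(x -> y) for the coordinate-wise Barker kernel.

    Per coordinate: log 2 + log mu_sigma(y_i - x_i) - softplus(-(y_i-x_i) grad_i),
    summed over coordinates.  The normalizer 2 is exact (the Barker balancing
    function has Z = 1/2 for any symmetric noise).
    """
    z = np.asarray(y, float) - np.asarray(x, float)
    s = scales.effective()
    terms = np.log(2.0) + log_normal_pdf(z, s) - softplus(-z * np.asarray(grad_x, float))
    return np.sum(terms, axis=-1)


def mh_log_ratio_barker(state_x: ChainState, state_y: ChainState, scales: ProposalScales):
    """log MH ratio for a Barker proposal using only cached gradients.

    log pi(y) - log pi(x) + sum_i [softplus applied to -z_i grad_x,i minus
    softplus applied to z_i grad_y,i] with z = y - x; the noise factors
    cancel by symmetry.  Equals the generic Hastings ratio computed from
    barker_log_density in both directions.
    """
    z = state_y.x - state_x.x
    corr = softplus(-z * state_x.grad) - softplus(z * state_y.grad)
    return state_y.logpi - state_x.logpi + np.sum(corr, axis=-1)


# ---------------------------------------------------------------------------
# baselines


def rwm_propose(state: ChainState, scales: ProposalScales, rng: Generator) -> np.ndarray:
    s = scales.effective()
    return state.x + s * rng.standard_normal(state.x.shape)


def mala_propose(state: ChainState, scales: ProposalScales, rng: Generator):
    """Langevin proposal y = x + (sigma s)^2/2 grad + sigma s xi.

    Returns (y, log forward density); the reverse density is evaluated at
    the proposed state for the Hastings ratio.
    """
    s = scales.effective()
    mean = state.x + 0.5 * s**2 * state.grad
    y = mean + s * rng.standard_normal(state.x.shape)
    return y, np.sum(log_normal_pdf(y - mean, s), axis=-1)


def mala_log_density(x, grad_x, y, scales: ProposalScales):
    s = scales.effective()
    mean = np.asarray(x, float) + 0.5 * s**2 * np.asarray(grad_x, float)
    return np.sum(log_normal_pdf(np.asarray(y, float) - mean, s), axis=-1)


def global_flip_propose(state: ChainState, scales: ProposalScales, rng: Generator) -> np.ndarray:
    """Barker variant with a single global sign flip: draw z ~ mu_sigma on R^d
    and return x + z with probability 1/(1+exp(-z.grad)), else x - z."""
    s = scales.effective()
    z = s * rng.standard_normal(state.x.shape)
    p = expit(np.sum(z * state.grad, axis=-1))
    b = np.where(rng.uniform(size=p.shape) <= p, 1.0, -1.0)
    return state.x + b[..., None] * z


def global_flip_log_density(x, grad_x, y, scales: ProposalScales):
    z = np.asarray(y, float) - np.asarray(x, float)
    s = scales.effective()
    lognoise = np.sum(log_normal_pdf(z, s), axis=-1)
    return np.log(2.0) + lognoise - softplus(-np.sum(z * np.asarray(grad_x, float), axis=-1))


def hmc_propose(
    state: ChainState,
    scales: ProposalScales,
    L: int,
    rng: Generator,
    target: TargetDensity,
) -> "ProposalOutcome":
    """Fixed-L Hamiltonian proposal: leapfrog with per-coordinate step
    sigma s_i and identity mass; acceptance uses the leapfrog energy error.

    L = 1 coincides with MALA in both proposal law and acceptance
    probability.  Non-finite energies mid-trajectory yield accept_prob 0.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    s = scales.effective()
    xi0 = rng.standard_normal(state.x.shape)
    xi = xi0 + 0.5 * s * state.grad
    x = state.x + s * xi
    for _ in range(L - 1):
        g = target.grad_log_density(x)
        xi = xi + s * g
        x = x + s * xi
    logpi_y = target.log_density(x)
    grad_y = target.grad_log_density(x)
    xi = xi + 0.5 * s * grad_y
    with np.errstate(invalid="ignore"):
        log_ratio = (
            logpi_y
            - state.logpi
            + 0.5 * np.sum(xi0 * xi0, axis=-1)
            - 0.5 * np.sum(xi * xi, axis=-1)
        )
    log_ratio = np.where(np.isfinite(log_ratio), log_ratio, -np.inf)
    y_state = ChainState(x=x, logpi=logpi_y, grad=grad_y)
    accept_prob = np.exp(np.minimum(0.0, log_ratio))
    return y_state, log_ratio, accept_prob


# ---------------------------------------------------------------------------
# Metropolis-Hastings step


def mh_step(
    state: ChainState,
    kind: str,
    scales: ProposalScales,
    rng: Generator,
    target: TargetDensity,
    L: Optional[int] = None,
) -> tuple[ChainState, ProposalOutcome]:
    """One Metropolis-Hastings transition of the requested kind.

    Returns the (possibly unchanged) new state and the full proposal
    outcome; accept_prob is always the Rao-Blackwellised alpha(x, Y), which
    adaptation and ESJD estimators consume even on rejection.  A proposal
    with non-finite log-density is rejected with accept_prob 0.
    """
    if kind == "hmc":
        y_state, log_ratio, _ = hmc_propose(state, scales, L or 1, rng, target)
    else:
        if kind == "barker":
            y = barker_propose(state, scales, rng)
        elif kind == "rwm":
            y = rwm_propose(state, scales, rng)
        elif kind == "mala":
            y, _ = mala_propose(state, scales, rng)
        elif kind == "global_flip":
            y = global_flip_propose(state, scales, rng)
        else:
            raise ValueError(f"unknown sampler kind: {kind!r}")
        y_state = ChainState(
            x=y, logpi=target.log_density(y), grad=target.grad_log_density(y)
        )
        if kind == "barker":
            log_ratio = mh_log_ratio_barker(state, y_state, scales)
        elif kind == "rwm":
            log_ratio = y_state.logpi - state.logpi
        elif kind == "mala":
            fwd = mala_log_density(state.x, state.grad, y_state.x, scales)
            rev = mala_log_density(y_state.x, y_state.grad, state.x, scales)
            log_ratio = y_state.logpi - state.logpi + rev - fwd
        else:  # global_flip
            fwd = global_flip_log_density(state.x, state.grad, y_state.x, scales)
            rev = global_flip_log_density(y_state.x, y_state.grad, state.x, scales)
            log_ratio = y_state.logpi - state.logpi + rev - fwd
    with np.errstate(invalid="ignore"):
        log_ratio = np.where(np.isfinite(y_state.logpi), log_ratio, -np.inf)
        log_ratio = np.where(np.isfinite(log_ratio), log_ratio, -np.inf)
    accept_prob = np.exp(np.minimum(0.0, log_ratio))
    accepted = rng.uniform(size=np.shape(accept_prob)) < accept_prob
    mask = accepted[..., None] if state.x.ndim > np.ndim(accept_prob) else accepted
    new = ChainState(
        x=np.where(mask, y_state.x, state.x),
        logpi=np.where(accepted, y_state.logpi, state.logpi),
        grad=np.where(mask, y_state.grad, state.grad),
    )
    outcome = ProposalOutcome(
        y=y_state, log_mh_ratio=log_ratio, accept_prob=accept_prob, accepted=accepted
    )
    return new, outcome
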