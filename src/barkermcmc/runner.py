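"""Chain drivers: fixed-scale and adaptive Metropolis-Hastings runs.

Both drivers advance a batch of independent chains in lock step (state
shape ``(R, d)``), which keeps the per-iteration work in vectorized numpy
and makes repeated-run protocols cheap on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.random import Generator

from .adaptation import AdaptState, adapt_update, effective_scales, init_adapt_state
from .proposals import ChainState, ProposalScales, make_state, mh_step
from .targets import TargetDensity

__all__ = ["RunRecord", "AdaptiveRunRecord", "run_chain", "run_adaptive_chain"]


@dataclass
class RunRecord:
    """Raw output of a fixed-scale run: positions, proposals and the
    Rao-Blackwellised acceptance probabilities, all of length T."""

    chain: np.ndarray  # (T, ..., d)
    accept_probs: np.ndarray  # (T, ...)
    proposals: np.ndarray  # (T, ..., d)
    seed: int = -1
    adapt_trace: Optional[dict] = None

    def __post_init__(self):
        T = self.chain.shape[0]
        if self.accept_probs.shape[0] != T or self.proposals.shape[0] != T:
            raise ValueError("all arrays must share length T")


@dataclass
class AdaptiveRunRecord:
    """Output of an adaptive run.

    ``log_var_trace`` stores log Sigma_t,ii per iteration (float32), which
    the tuning-distance metric d_t consumes; ``log_sigma_trace`` tracks the
    global scale.
    """

    chain: np.ndarray  # (T, R, d) float32
    accept_probs: np.ndarray  # (T, R)
    log_sigma_trace: np.ndarray  # (T, R)
    log_var_trace: Optional[np.ndarray]  # (T, R, d) float32
    final_adapt: AdaptState
    kind: str = ""
    n_grad_evals_per_chain: int = 0


def run_chain(
    target: TargetDensity,
    kind: str,
    scales: ProposalScales,
    n_iter: int,
    rng: Generator,
    x0: np.ndarray,
    L: Optional[int] = None,
) -> RunRecord:
    """Run n_iter MH steps at fixed scales from x0 (batched over leading axes)."""
    state = make_state(target, np.asarray(x0, float))
    T = int(n_iter)
    chain = np.empty((T, *state.x.shape))
    props = np.empty((T, *state.x.shape))
    aps = np.empty((T, *np.shape(state.logpi)))
    for t in range(T):
        state, out = mh_step(state, kind, scales, rng, target, L=L)
        aps[t] = out.accept_prob
        chain[t] = state.x
        props[t] = out.y.x
    return RunRecord(chain=chain, accept_probs=aps, proposals=props)


def run_adaptive_chain(
    target: TargetDensity,
    kind: str,
    n_iter: int,
    rng: Generator,
    n_chains: int = 1,
    kappa: float = 0.6,
    init_sd: float = 10.0,
    x0: Optional[np.ndarray] = None,
    keep_var_trace: bool = True,
    keep_chain: bool = True,
    chain_dtype=np.float32,
    log_every: int = 0,
) -> AdaptiveRunRecord:
    """Run R adaptive chains with Robbins-Monro tuning of sigma_t and the
    diagonal pre-conditioner.

    Chains start iid N(0, init_sd^2) coordinate-wise unless ``x0`` is given
    (e.g. prior draws for posterior targets).  Each iteration costs one
    fresh target density-and-gradient evaluation per chain.
    """
    d = target.dim
    R = int(n_chains)
    if x0 is None:
        x0 = init_sd * rng.standard_normal((R, d))
    state = make_state(target, np.asarray(x0, float))
    astate = init_adapt_state(kind, d, batch=(R,), kappa=kappa)
    T = int(n_iter)
    chain = np.empty((T, R, d), dtype=chain_dtype) if keep_chain else None
    aps = np.empty((T, R))
    ls_trace = np.empty((T, R))
    lv_trace = np.empty((T, R, d), dtype=np.float32) if keep_var_trace else None
    for t in range(T):
        scales = ProposalScales(
            sigma=np.exp(astate.log_sigma),
            coord_scale=np.sqrt(np.maximum(astate.var_diag, astate.var_floor)),
        )
        state, out = mh_step(state, kind, scales, rng, target)
        astate = adapt_update(astate, state.x, out.accept_prob)
        aps[t] = out.accept_prob
        ls_trace[t] = astate.log_sigma
        if keep_var_trace:
            lv_trace[t] = np.log(astate.var_diag)
        if keep_chain:
            chain[t] = state.x
        if log_every and (t + 1) % log_every == 0:
            lo = max(0, t + 1 - log_every)
            print(
                f"[{kind}] iter {t + 1}/{T}  sigma_t={float(np.exp(astate.log_sigma).mean()):.4g}"
                f"  accept_rate={float(aps[lo : t + 1].mean()):.3f}",
                flush=True,
            )
    return AdaptiveRunRecord(
        chain=chain if keep_chain else np.empty((0, R, d), dtype=chain_dtype),
        accept_probs=aps,
        log_sigma_trace=ls_trace,
        log_var_trace=lv_trace,
        final_adapt=astate,
        kind=kind,
        n_grad_evals_per_chain=T,
    )
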