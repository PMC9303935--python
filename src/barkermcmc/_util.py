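"""Shared numerical helpers: stable softplus/logistic forms, RNG plumbing,
and grid-based inverse-CDF sampling for one-dimensional densities."""

from __future__ import annotations

from typing import Callable

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

__all__ = [
    "softplus",
    "log_normal_pdf",
    "rng_from",
    "spawn_seed",
    "GridInverseCdf",
]


def softplus(u: np.ndarray | float) -> np.ndarray | float:
    """log(1 + e^u) through the overflow-safe branch max(u,0) + log1p(e^-|u|).

    Arguments with |u| ~ 1e4 occur routinely (large gradients times step
    draws), where the naive form overflows.
    """
    return np.logaddexp(0.0, u)


def log_normal_pdf(z, sigma):
    """Elementwise log N(z; 0, sigma^2)."""
    sigma = np.asarray(sigma, dtype=float)
    return -0.5 * (z / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def rng_from(seed: int | Generator, *key: int) -> Generator:
    """Derive an independent Generator from an integer seed plus a stream key.

    Passing a Generator through unchanged allows callers to thread an
    existing stream.
    """
    if isinstance(seed, Generator):
        return seed
    return default_rng(SeedSequence([int(seed), *map(int, key)]))


def spawn_seed(seed: int, *key: int) -> int:
    """A reproducible 31-bit child seed for APIs that want a plain integer."""
    return int(SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))


class GridInverseCdf:
    """Inverse-CDF sampler for an unnormalized 1-d log-density on a grid.

    The grid is widened geometrically until the captured probability mass
    (relative to the running total) stops changing at the requested level;
    quantiles are then obtained by monotone interpolation of the trapezoid
    CDF.  Used for exact stationary draws from densities without closed-form
    samplers (hyperbolic coordinates, generic locally balanced kernels).
    """

    def __init__(
        self,
        logpdf: Callable[[np.ndarray], np.ndarray],
        halfwidth: float = 20.0,
        center: float = 0.0,
        n_grid: int = 4097,
        mass_tol: float = 1e-10,
        max_expand: int = 60,
    ):
        hw = float(halfwidth)
        prev_mass = None
        for _ in range(max_expand):
            x = np.linspace(center - hw, center + hw, n_grid)
            lp = np.asarray(logpdf(x), dtype=float)
            lp = lp - np.max(lp[np.isfinite(lp)])
            p = np.exp(lp)
            mass = np.trapezoid(p, x)
            edge = max(p[0], p[-1]) * 2 * hw
            if prev_mass is not None and edge <= mass_tol * mass:
                break
            prev_mass = mass
            hw *= 1.6
        else:
            raise RuntimeError("inverse-CDF grid failed to capture the density mass")
        cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * 0.5 * np.diff(x))])
        self.norm = cdf[-1]
        if not np.isfinite(self.norm) or self.norm <= 0:
            raise RuntimeError("density mass is not positive and finite")
        self.x = x
        self.cdf = cdf / self.norm
        self.pdf = p / self.norm

    def ppf(self, u):
        return np.interp(u, self.cdf, self.x)

    def cdf_at(self, q):
        return np.interp(q, self.x, self.cdf)

    def sample(self, rng: Generator, size) -> np.ndarray:
        return self.ppf(rng.uniform(size=size))

    def mean_var(self) -> tuple[float, float]:
        m = np.trapezoid(self.x * self.pdf, self.x)
        v = np.trapezoid((self.x - m) ** 2 * self.pdf, self.x)
        return float(m), float(v)
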