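"""Minimal denoising-diffusion machinery with measurement-guided sampling.

The forward process corrupts a sample x0 over T steps,
``q(x_t | x_{t-1}) = N(sqrt(1-beta_t) x_{t-1}, beta_t I)``, with the closed
form marginal ``x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps``. The reverse
process steps back with a noise estimate eps_hat:

    x_{t-1} = (x_t - (1-alpha_t)/sqrt(1-abar_t) * eps_hat) / sqrt(alpha_t)
              + sigma_t * z

Guided sampling adds a conditional drift toward a scalar measurement target
y0: the reverse-step result is shifted by ``weight * grad_x[-(y(x)-y0)^2]``
evaluated at x_t, which pushes samples toward measurements near y0 (here the
measurement of interest is the marginal reflex ratio of the decoded image;
the guidance function itself is pluggable).

No network is trained anywhere in this package — the workflow is
training-free. This sampler exists so the conditioning mathematics is
testable end-to-end on analytic toys where the exact noise estimate is known
in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError, GuidanceError

__all__ = [
    "NoiseSchedule",
    "GuidanceConfig",
    "build_schedule",
    "forward_sample",
    "reverse_step",
    "guided_reverse_step",
    "reverse_chain",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step variance sequences over T steps (arrays indexed by t-1)."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    sigma: np.ndarray

    def _check_t(self, t: int) -> None:
        if not (1 <= t <= self.T):
            raise ConfigurationError(f"step t={t} outside [1, {self.T}]")


def build_schedule(
    T: int, beta_start: float = 1e-4, beta_end: float = 0.02
) -> NoiseSchedule:
    """Linear beta schedule; sigma_t^2 = beta_t (the standard choice)."""
    if T < 1:
        raise ConfigurationError("T must be >= 1")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ConfigurationError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})"
        )
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    sigma = np.sqrt(beta)
    return NoiseSchedule(T, beta, alpha, alpha_bar, sigma)


def forward_sample(
    x0: np.ndarray | float,
    t: int,
    schedule: NoiseSchedule,
    noise: np.ndarray | float,
) -> np.ndarray:
    """Closed-form forward marginal draw at step t given standard-normal noise."""
    schedule._check_t(t)
    ab = schedule.alpha_bar[t - 1]
    return np.sqrt(ab) * np.asarray(x0) + np.sqrt(1.0 - ab) * np.asarray(noise)


def reverse_step(
    xt: np.ndarray | float,
    t: int,
    eps_estimate: np.ndarray | float,
    schedule: NoiseSchedule,
    z: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One reverse transition; z is forced to 0 at the final step t=1."""
    schedule._check_t(t)
    a = schedule.alpha[t - 1]
    ab = schedule.alpha_bar[t - 1]
    if t == 1:
        z = 0.0
    mean = (np.asarray(xt) - (1.0 - a) / np.sqrt(1.0 - ab) * np.asarray(eps_estimate)) / np.sqrt(a)
    return mean + schedule.sigma[t - 1] * np.asarray(z)


@dataclass
class GuidanceConfig:
    """Conditional-drift configuration for measurement-guided sampling.

    ``measure`` maps a sample to the scalar measurement y; ``grad`` is its
    gradient when known analytically (e.g. linear measurements), otherwise
    central finite differences with step ``fd_step`` are used.
    """

    y0: float
    weight: float
    measure: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray] | None = None
    fd_step: float = 1e-3

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigurationError("guidance weight must be >= 0")


def _measurement_gradient(x: np.ndarray, cfg: GuidanceConfig) -> np.ndarray:
    if cfg.grad is not None:
        return np.asarray(cfg.grad(x), dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        hi = x.copy()
        lo = x.copy()
        hi[idx] += cfg.fd_step
        lo[idx] -= cfg.fd_step
        g[idx] = (cfg.measure(hi) - cfg.measure(lo)) / (2.0 * cfg.fd_step)
        it.iternext()
    return g


def guided_reverse_step(
    xt: np.ndarray | float,
    t: int,
    eps_estimate: np.ndarray | float,
    schedule: NoiseSchedule,
    guidance: GuidanceConfig,
    z: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Reverse step plus the conditional drift weight * grad[-(y - y0)^2].

    With weight = 0 the result is bit-identical to the unguided step.
    """
    base = reverse_step(xt, t, eps_estimate, schedule, z)
    if guidance.weight == 0.0:
        return base
    x = np.atleast_1d(np.asarray(xt, dtype=float))
    y = float(guidance.measure(x))
    drift = -2.0 * (y - guidance.y0) * _measurement_gradient(x, guidance)
    if not np.all(np.isfinite(drift)):
        raise GuidanceError(
            f"non-finite guidance gradient at t={t} (y={y}, y0={guidance.y0})"
        )
    out = np.asarray(base) + guidance.weight * drift.reshape(np.shape(base))
    return out


def reverse_chain(
    xT: np.ndarray | float,
    schedule: NoiseSchedule,
    eps_fn: Callable[[np.ndarray, int], np.ndarray],
    rng: np.random.Generator | None = None,
    guidance: GuidanceConfig | None = None,
) -> np.ndarray:
    """Run the full reverse process from x_T down to x_0.

    ``eps_fn(x, t)`` supplies the noise estimate; with ``rng`` omitted the
    chain is deterministic (z = 0 at every step).
    """
    x = np.asarray(xT, dtype=float)
    for t in range(schedule.T, 0, -1):
        z = rng.standard_normal(np.shape(x)) if (rng is not None and t > 1) else 0.0
        eps = eps_fn(x, t)
        if guidance is not None:
            x = guided_reverse_step(x, t, eps, schedule, guidance, z)
        else:
            x = reverse_step(x, t, eps, schedule, z)
    return x


def gaussian_eps_estimate(
    xt: np.ndarray | float, t: int, schedule: NoiseSchedule, mu: float, sigma0: float
) -> np.ndarray:
    """Exact posterior-mean noise estimate for Gaussian data x0 ~ N(mu, sigma0^2).

    E[eps | x_t] = sqrt(1-abar_t) (x_t - sqrt(abar_t) mu) /
                   (abar_t sigma0^2 + 1 - abar_t).
    This is the analytic stand-in for a trained denoiser on the Gaussian toy.
    """
    ab = schedule.alpha_bar[t - 1]
    denom = ab * sigma0**2 + 1.0 - ab
    return np.sqrt(1.0 - ab) * (np.asarray(xt) - np.sqrt(ab) * mu) / denom
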