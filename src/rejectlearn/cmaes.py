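"""Covariance-matrix-adaptation evolution strategy (CMA-ES).

A derivative-free minimizer that samples each generation's candidate
solutions from a multivariate normal distribution N(m, sigma^2 C), ranks them
by objective value, recombines the mu best into the next mean, and adapts
both the global step size sigma (via the conjugate evolution path p_sigma)
and the covariance matrix C (rank-one update via the evolution path p_c plus
a rank-mu update from the selected steps).  Strategy constants (selection
weights, mu_eff, learning rates c_sigma, d_sigma, c_c, c_1, c_mu) take their
standard defaults, so the only parameters a caller normally touches are the
initial mean, the initial step size and the stopping rules.

Here the search space is the 3-vector of rejection thresholds, but the
implementation is dimension-generic.

Stopping conditions, checked each generation in this order:

1. ``lower_bound``  – the best objective value reached ``f_lower_bound``
   (optimum found, e.g. 0 for perfect discrimination objectives);
2. ``stall_delta``  – the objective spread within the current population fell
   below ``stall_delta`` (population has collapsed onto a local optimum);
3. ``long_stall``   – the best value changed by less than ``long_stall_alpha``
   (< stall_delta) over the last ``long_stall_span`` generations;
4. ``max_generations``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import ConfigurationError

__all__ = ["CMAESConfig", "CMAESResult", "cmaes_minimize"]


@dataclass
class CMAESConfig:
    """Run parameters for :func:`cmaes_minimize`.

    ``population_size`` (lambda) and ``parent_count`` (mu) default to the
    standard ``4 + floor(3 ln n)`` and ``lambda // 2``.  ``bounds`` is carried
    as metadata for callers that wrap the objective with a box penalty; the
    optimizer itself is unconstrained.
    """

    initial_mean: Sequence[float] = (0.7, 0.3, 0.2)
    initial_step: float = 0.2
    population_size: int | None = None
    parent_count: int | None = None
    bounds: tuple[float, float] = (0.0, 1.0)
    f_lower_bound: float = 0.0
    stall_delta: float = 1e-4
    long_stall_alpha: float = 1e-5
    long_stall_span: int = 20
    max_generations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_step <= 0:
            raise ConfigurationError("initial_step must be positive")
        if self.stall_delta <= 0 or self.long_stall_alpha <= 0:
            raise ConfigurationError("stall tolerances must be positive")
        if self.long_stall_alpha >= self.stall_delta:
            raise ConfigurationError("long_stall_alpha must be < stall_delta")
        if self.long_stall_span < 1:
            raise ConfigurationError("long_stall_span must be >= 1")
        if self.population_size is not None and self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        lo, hi = self.bounds
        if not all(lo <= v <= hi for v in self.initial_mean):
            raise ConfigurationError("initial_mean must lie within bounds")


@dataclass
class CMAESResult:
    best_x: np.ndarray
    best_f: float
    generations: int
    stop_reason: str
    history: list[float] = field(default_factory=list)  # best f per generation


def cmaes_minimize(
    objective: Callable[[np.ndarray], float], config: CMAESConfig
) -> CMAESResult:
    """Minimize ``objective`` over R^n starting from ``config.initial_mean``.

    Deterministic for a fixed ``config.seed``.  Raises if the objective
    returns a non-finite value.
    """
    rng = np.random.default_rng(config.seed)
    m = np.asarray(config.initial_mean, dtype=float).copy()
    n = m.size
    sigma = float(config.initial_step)

    lam = config.population_size or (4 + int(3 * math.log(n)))
    mu = config.parent_count or lam // 2
    if mu < 1 or mu > lam:
        raise ConfigurationError("parent_count must satisfy 1 <= mu <= lambda")

    # selection weights and effective mass
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)

    # strategy constants (standard defaults)
    c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    p_sigma = np.zeros(n)
    p_c = np.zeros(n)
    C = np.eye(n)

    best_x = m.copy()
    best_f = float(objective(m))
    if not math.isfinite(best_f):
        raise ConfigurationError("objective returned a non-finite value")
    history: list[float] = []
    stop_reason = "max_generations"
    gen = 0

    for gen in range(1, config.max_generations + 1):
        # keep C symmetric positive-definite under float drift
        C = (C + C.T) / 2
        eigvals, B = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        D = np.sqrt(eigvals)

        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T          # y_i ~ N(0, C)
        X = m + sigma * y
        f = np.empty(lam)
        for i in range(lam):
            f[i] = objective(X[i])
            if not math.isfinite(f[i]):
                raise ConfigurationError("objective returned a non-finite value")

        order = np.argsort(f, kind="stable")
        f_sorted = f[order]
        if f_sorted[0] < best_f:
            best_f = float(f_sorted[0])
            best_x = X[order[0]].copy()
        history.append(float(f_sorted[0]))

        # recombination
        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        m = m + sigma * y_w

        # step-size path (conjugate): uses C^{-1/2} y_w
        c_inv_sqrt_y = B @ ((B.T @ y_w) / D)
        p_sigma = (1 - c_sigma) * p_sigma + math.sqrt(
            c_sigma * (2 - c_sigma) * mu_eff
        ) * c_inv_sqrt_y
        h_sigma = float(
            np.linalg.norm(p_sigma)
            / math.sqrt(1 - (1 - c_sigma) ** (2 * gen))
            < (1.4 + 2 / (n + 1)) * chi_n
        )
        p_c = (1 - c_c) * p_c + h_sigma * math.sqrt(
            c_c * (2 - c_c) * mu_eff
        ) * y_w

        # covariance update: rank-one plus rank-mu
        rank_one = np.outer(p_c, p_c)
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        delta_h = (1 - h_sigma) * c_c * (2 - c_c)
        C = (
            (1 - c_1 - c_mu) * C
            + c_1 * (rank_one + delta_h * C)
            + c_mu * rank_mu
        )

        sigma *= math.exp((c_sigma / d_sigma) * (np.linalg.norm(p_sigma) / chi_n - 1))

        # stopping rules
        if best_f <= config.f_lower_bound:
            stop_reason = "lower_bound"
            break
        if float(f_sorted[-1] - f_sorted[0]) < config.stall_delta:
            stop_reason = "stall_delta"
            break
        if len(history) >= config.long_stall_span:
            window = history[-config.long_stall_span :]
            if max(window) - min(window) < config.long_stall_alpha:
                stop_reason = "long_stall"
                break

    return CMAESResult(
        best_x=best_x,
        best_f=best_f,
        generations=gen,
        stop_reason=stop_reason,
        history=history,
    )
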