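"""Discrete-time replicator dynamics for the cooperator/cheat game.

This is the numerical counterpart of every closed form in
:mod:`cheatsplit.game`: each generation a strategy's frequency is multiplied
by its fitness relative to the population mean,

    x_i' = x_i W_i / W_mean,

which shares its fixed points with the continuous-time replicator equation
while matching the generational life cycle of a lytic virus.  The module is
used as an independent oracle in the test-suite and behind the
``equilibria --numeric`` command; finite-population stochasticity is the job
of :mod:`cheatsplit.abm`, not this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .game import (
    CoinfectionParameters,
    PayoffParameters,
    PopulationState,
    fitnesses,
)

__all__ = [
    "OracleSettings",
    "IterationResult",
    "PopulationCollapseError",
    "replicator_step",
    "iterate",
    "oracle_regime",
    "batch_oracle_regime",
    "batch_fixed_point_residual",
]


class PopulationCollapseError(RuntimeError):
    """Mean fitness reached zero: nothing reproduces."""


@dataclass(frozen=True)
class OracleSettings:
    """Iteration control for the oracle.

    ``rare_frequency`` is the frequency at which an invading mutant is
    introduced (small enough to count as rare, large enough for doubles).
    """

    initial_state: PopulationState
    rare_frequency: float = 1e-6
    tolerance: float = 1e-12
    max_iterations: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 < self.rare_frequency <= 0.01:
            raise ValueError("rare_frequency must lie in (0, 0.01]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class IterationResult:
    state: PopulationState
    converged: bool
    iterations: int


def replicator_step(
    state: PopulationState,
    params: PayoffParameters,
    coinf: CoinfectionParameters,
) -> PopulationState:
    """One generation of the multiplicative replicator map."""
    wc, w1, w2 = fitnesses(params, state, coinf)
    x = state.as_array()
    w = np.array([wc, w1, w2])
    mean_w = float(x @ w)
    if mean_w <= 0.0:
        raise PopulationCollapseError("mean fitness is zero: population collapse")
    return PopulationState.from_array(x * w / mean_w)


def iterate(
    settings: OracleSettings,
    params: PayoffParameters,
    coinf: CoinfectionParameters,
) -> IterationResult:
    """Iterate until the largest per-step frequency change drops below the
    tolerance or the iteration cap is reached."""
    state = settings.initial_state
    for it in range(1, settings.max_iterations + 1):
        nxt = replicator_step(state, params, coinf)
        delta = np.max(np.abs(nxt.as_array() - state.as_array()))
        state = nxt
        if delta < settings.tolerance:
            return IterationResult(state, True, it)
    return IterationResult(state, False, settings.max_iterations)


def rare_invasion_start(rare_frequency: float = 1e-6) -> PopulationState:
    """Cooperator resident with both cheats introduced at rare frequency."""
    r = rare_frequency
    return PopulationState(1.0 - 2.0 * r, r, r)


def oracle_regime(
    params: PayoffParameters,
    coinf: CoinfectionParameters,
    *,
    rare_frequency: float = 1e-6,
    tolerance: float = 1e-13,
    max_iterations: int = 400_000,
    extinction_cut: float = 1e-4,
) -> str:
    """Classify the long-run outcome purely by iteration from a
    cooperator-resident start with both cheats rare.

    Returns ``multipartite`` when the cooperator frequency falls below
    ``extinction_cut``, ``cooperator_only`` when both cheats decline below
    their introduction frequency, and ``coexistence`` otherwise.
    """
    settings = OracleSettings(
        initial_state=rare_invasion_start(rare_frequency),
        rare_frequency=rare_frequency,
        tolerance=tolerance,
        max_iterations=max_iterations,
    )
    res = iterate(settings, params, coinf)
    s = res.state
    if s.p < extinction_cut:
        return "multipartite"
    if s.q < rare_frequency / 10.0 and s.z < rare_frequency / 10.0:
        return "cooperator_only"
    return "coexistence"


def batch_oracle_regime(
    params_table: np.ndarray,
    beta: np.ndarray,
    *,
    rare_frequency: float = 1e-6,
    n_steps: int = 60_000,
    extinction_cut: float = 1e-4,
) -> np.ndarray:
    """Vectorised :func:`oracle_regime` over many parameter draws.

    All systems are iterated in lock-step from the cooperator-resident
    start; classification follows the same cuts as the scalar version.
    Away from the regime boundaries the replicator map contracts
    geometrically, so a fixed step budget suffices.
    """
    a, b, c, d, e = params_table.T
    n = len(beta)
    r = rare_frequency
    p = np.full(n, 1.0 - 2.0 * r)
    q = np.full(n, r)
    z = np.full(n, r)
    for _ in range(n_steps):
        wc = a * (1 - beta) + beta * (c * q + c * z + d * p)
        w1 = beta * (b * p + e * z)
        w2 = beta * (b * p + e * q)
        mean_w = p * wc + q * w1 + z * w2
        p, q, z = p * wc / mean_w, q * w1 / mean_w, z * w2 / mean_w
    out = np.where(
        p < extinction_cut,
        "multipartite",
        np.where((q < r / 10) & (z < r / 10), "cooperator_only", "coexistence"),
    )
    return out


def batch_fixed_point_residual(
    states: np.ndarray,
    params_table: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Vectorised one-step residual ``max_i |x_i' - x_i|`` for many parameter
    draws at once.

    ``states`` is (n, 3); ``params_table`` is (n, 5) columns (a, b, c, d, e);
    ``beta`` is (n,).  A residual at the level of rounding error certifies
    that the state is a fixed point of the replicator map.
    """
    p, q, z = states.T
    a, b, c, d, e = params_table.T
    wc = a * (1 - beta) + beta * (c * q + c * z + d * p)
    w1 = beta * (b * p + e * z)
    w2 = beta * (b * p + e * q)
    mean_w = p * wc + q * w1 + z * w2
    nxt = np.stack([p * wc, q * w1, z * w2], axis=1) / mean_w[:, None]
    return np.max(np.abs(nxt - states), axis=1)
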