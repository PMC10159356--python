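"""Closed-form analysis of the cooperator / complementing-cheat game.

A well-mixed viral population infects host cells either singly (with
probability ``1 - beta``) or doubly (with probability ``beta``).  Three
genome strategies compete:

* ``C``  -- the full-length cooperator, encoding both shared gene products;
* ``D1`` -- a cheat lacking the second gene product;
* ``D2`` -- a cheat lacking the first gene product.

A lone cooperator yields ``a`` progeny.  In coinfection a cooperator earns
``d`` against another cooperator and ``c`` against a cheat, while the cheat
earns ``b`` against a cooperator.  Two *complementary* cheats provision each
other in trans and each earn ``e``; two identical cheats abort the infection
(payoff 0), as does any lone cheat.  With full coinfection (``beta = 1``)
and a single cheat type this is exactly the Hawk-Dove / Snowdrift game.

The module provides the fitness functions, the cheat-invasion threshold, the
single- and two-cheat equilibria, the complementation threshold ``e*`` above
which both cheats jointly drive the cooperator extinct (the transition to a
multipartite population), the productivity threshold ``e**`` below which the
resulting multipartite population is *less* productive than its monopartite
ancestor, and phase-diagram grids over (beta, e/d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PayoffParameters",
    "CoinfectionParameters",
    "PopulationState",
    "ThresholdSet",
    "EquilibriumResult",
    "RegimeGrid",
    "COOPERATOR_ONLY",
    "COEXISTENCE",
    "MULTIPARTITE",
    "COMPLEMENTATION_DRIVEN",
    "NoInteriorEquilibriumError",
    "DegenerateParameterError",
    "fitnesses",
    "invasion_threshold",
    "single_cheat_equilibrium",
    "two_cheat_equilibrium",
    "e_star",
    "e_star_star",
    "thresholds",
    "classify_regime",
    "multipartite_less_productive",
    "regime_grid",
]

#: Regime labels returned by :func:`classify_regime`.
COOPERATOR_ONLY = "cooperator_only"
COEXISTENCE = "coexistence"
MULTIPARTITE = "multipartite"
COMPLEMENTATION_DRIVEN = "complementation_driven"

_SIMPLEX_TOL = 1e-12


class NoInteriorEquilibriumError(ValueError):
    """Raised when the requested interior equilibrium does not exist."""


class DegenerateParameterError(ValueError):
    """Raised when a closed form has a vanishing denominator."""


@dataclass(frozen=True)
class PayoffParameters:
    """The five payoffs of the three-strategy game (progeny units).

    Constraints ``d >= a > c > 0``, ``e >= 0`` and ``b > 0`` are enforced at
    construction: cooperators do at least as well against each other as
    alone, and are outcompeted but not driven negative by cheats.
    """

    a: float
    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not (self.d >= self.a > self.c > 0):
            raise ValueError(
                f"payoffs must satisfy d >= a > c > 0, got "
                f"a={self.a}, c={self.c}, d={self.d}"
            )
        if self.e < 0:
            raise ValueError(f"complementation payoff e must be >= 0, got {self.e}")
        if self.b <= 0:
            raise ValueError(f"cheat payoff b must be > 0, got {self.b}")

    def with_e(self, e: float) -> "PayoffParameters":
        """Return a copy with the complementation payoff replaced."""
        return PayoffParameters(self.a, self.b, self.c, self.d, e)


@dataclass(frozen=True)
class CoinfectionParameters:
    """Coinfection intensity: either beta (probability a cell receives two
    genomes) or the Poisson multiplicity of infection ``moi``; supplying one
    determines the other (see :mod:`cheatsplit.empirical`)."""

    beta: Optional[float] = None
    moi: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.beta is None) == (self.moi is None):
            raise ValueError("supply exactly one of beta, moi")
        if self.moi is not None:
            if self.moi < 0:
                raise ValueError(f"moi must be >= 0, got {self.moi}")
            from .empirical import beta_from_moi

            object.__setattr__(self, "beta", float(beta_from_moi(self.moi)))
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class PopulationState:
    """Frequencies (p, q, z) of cooperator and the two cheats on the simplex."""

    p: float
    q: float
    z: float

    def __post_init__(self) -> None:
        if min(self.p, self.q, self.z) < 0:
            raise ValueError(f"negative frequency in ({self.p}, {self.q}, {self.z})")
        total = self.p + self.q + self.z
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"frequencies must sum to 1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.q, self.z], dtype=float)

    @staticmethod
    def from_array(x, *, clamp: bool = False) -> "PopulationState":
        x = np.asarray(x, dtype=float)
        if clamp:
            x = np.clip(x, 0.0, None)
        x = x / x.sum()
        return PopulationState(float(x[0]), float(x[1]), float(x[2]))


@dataclass(frozen=True)
class ThresholdSet:
    """The three analytic thresholds; ``None`` marks a threshold whose
    precondition fails (e.g. no invasion possible at any beta <= 1)."""

    beta_invasion: Optional[float]
    e_star: Optional[float]
    e_star_star: Optional[float]


@dataclass(frozen=True)
class EquilibriumResult:
    state: PopulationState
    kind: str
    stable: Optional[bool] = None


@dataclass(frozen=True)
class RegimeGrid:
    """Regime labels on a (beta, e/d) grid; ``regime[i, j]`` is the label at
    ``e_over_d_axis[i]``, ``beta_axis[j]``."""

    beta_axis: np.ndarray
    e_over_d_axis: np.ndarray
    regime: np.ndarray

    def __post_init__(self) -> None:
        if self.regime.shape != (len(self.e_over_d_axis), len(self.beta_axis)):
            raise ValueError("regime matrix shape does not match axes")


def fitnesses(
    params: PayoffParameters, state: PopulationState, coinf: CoinfectionParameters
) -> tuple[float, float, float]:
    """Expected progeny (W(C), W(D1), W(D2)) at the given population state.

    W(C)  = a(1-beta) + beta (c q + c z + d p)
    W(D1) = beta (b p + e z)
    W(D2) = beta (b p + e q)
    """
    a, b, c, d, e = params.a, params.b, params.c, params.d, params.e
    beta = coinf.beta
    p, q, z = state.p, state.q, state.z
    wc = a * (1.0 - beta) + beta * (c * q + c * z + d * p)
    w1 = beta * (b * p + e * z)
    w2 = beta * (b * p + e * q)
    return wc, w1, w2


def invasion_threshold(params: PayoffParameters) -> Optional[float]:
    """Minimum coinfection fraction above which a rare cheat invades a
    cooperator-only population, ``a / (a + b - d)``.

    Returns ``None`` when no invasion is possible at any beta <= 1, i.e.
    when ``b <= d`` (then a rare cheat never outgrows the residents).
    """
    a, b, d = params.a, params.b, params.d
    if b <= d:
        return None
    return a / (a + b - d)


def _require_invasion(params: PayoffParameters, coinf: CoinfectionParameters) -> float:
    thr = invasion_threshold(params)
    if thr is None or coinf.beta <= thr:
        raise NoInteriorEquilibriumError(
            "cheats cannot invade at this coinfection fraction "
            f"(beta={coinf.beta}, threshold={thr})"
        )
    return thr


def single_cheat_equilibrium(
    params: PayoffParameters,
    coinf: CoinfectionParameters,
    *,
    check_stability: bool = False,
) -> EquilibriumResult:
    """Cooperator / single-cheat coexistence equilibrium.

    p* = (a - a beta + c beta) / (beta (b + c - d)), q* = 1 - p*, z = 0.
    Requires the invasion condition (b > d and beta above threshold).
    """
    _require_invasion(params, coinf)
    a, b, c, d = params.a, params.b, params.c, params.d
    beta = coinf.beta
    denom = beta * (b + c - d)
    if denom == 0.0:
        raise DegenerateParameterError("b + c - d = 0: interior equilibrium undefined")
    p = (a - a * beta + c * beta) / denom
    p = min(max(p, 0.0), 1.0)
    state = PopulationState(p, 1.0 - p, 0.0)
    result = EquilibriumResult(state, "single_cheat_coexistence")
    if check_stability:
        result = EquilibriumResult(state, result.kind, _is_stable(state, params, coinf))
    return result


def two_cheat_equilibrium(
    params: PayoffParameters,
    coinf: CoinfectionParameters,
    *,
    check_stability: bool = False,
) -> EquilibriumResult:
    """Equilibrium once both complementary cheats have invaded.

    q* = z* = (a - (a + b - d) beta) / ((e - 2(b + c - d)) beta) and
    p* = 1 - 2 q*.  If the interior p* crosses zero the cooperator is driven
    extinct and the boundary state p = 0, q = z = 1/2 is returned with kind
    ``multipartite`` -- exactly the extinction argument behind e*.
    """
    _require_invasion(params, coinf)
    if params.e <= 0:
        raise NoInteriorEquilibriumError(
            "the second cheat needs e > 0 to invade (complementation required)"
        )
    a, b, c, d, e = params.a, params.b, params.c, params.d, params.e
    beta = coinf.beta
    denom = (e - 2.0 * (b + c - d)) * beta
    if denom == 0.0:
        raise DegenerateParameterError(
            "e - 2(b + c - d) = 0: two-cheat equilibrium undefined"
        )
    q = (a - (a + b - d) * beta) / denom
    p = 1.0 - 2.0 * q
    if p <= 0.0:
        state = PopulationState(0.0, 0.5, 0.5)
        kind = "multipartite"
    else:
        q = min(max(q, 0.0), 0.5)
        state = PopulationState(1.0 - 2.0 * q, q, q)
        kind = "two_cheat_coexistence"
    result = EquilibriumResult(state, kind)
    if check_stability:
        result = EquilibriumResult(state, kind, _is_stable(state, params, coinf))
    return result


def e_star(params: PayoffParameters, coinf: CoinfectionParameters) -> Optional[float]:
    """Minimum complementation payoff for the cheats to fully replace the
    cooperator: e* = (2a - 2a beta + 2c beta) / beta.  ``None`` at beta = 0
    (without coinfection there is no cheating at all)."""
    beta = coinf.beta
    if beta == 0.0:
        return None
    a, c = params.a, params.c
    return (2.0 * a - 2.0 * a * beta + 2.0 * c * beta) / beta


def e_star_star(params: PayoffParameters, coinf: CoinfectionParameters) -> Optional[float]:
    """Complementation level below which the multipartite population is less
    productive than its monopartite ancestor: e** = 2(d + a(-1 + 1/beta)).

    For any d > c, e** - e* = 2(d - c) > 0: a window (e*, e**) always exists
    in which multipartitism evolves yet lowers mean population fitness.
    """
    beta = coinf.beta
    if beta == 0.0:
        return None
    a, d = params.a, params.d
    return 2.0 * (d + a * (-1.0 + 1.0 / beta))


def thresholds(params: PayoffParameters, coinf: CoinfectionParameters) -> ThresholdSet:
    """Bundle the invasion, extinction and productivity thresholds."""
    return ThresholdSet(
        beta_invasion=invasion_threshold(params),
        e_star=e_star(params, coinf),
        e_star_star=e_star_star(params, coinf),
    )


def classify_regime(params: PayoffParameters, coinf: CoinfectionParameters) -> str:
    """Label the long-run outcome for one parameter set.

    * ``cooperator_only`` -- cheats cannot invade (b <= d, or beta at or
      below the invasion threshold);
    * ``complementation_driven`` -- cheats cannot invade individually
      (b <= d) but joint replacement remains possible through very strong
      complementation (e > b); flagged, not analysed further;
    * ``multipartite`` -- both cheats invade and e >= e* (boundary equality
      counts as multipartite);
    * ``coexistence`` -- cheats invade but cannot fully replace the
      cooperator.
    """
    thr = invasion_threshold(params)
    if thr is None or coinf.beta <= thr:
        if params.b <= params.d and params.e > params.b:
            return COMPLEMENTATION_DRIVEN
        return COOPERATOR_ONLY
    if params.e <= 0.0:
        return COEXISTENCE
    es = e_star(params, coinf)
    if es is not None and params.e >= es:
        return MULTIPARTITE
    return COEXISTENCE


def multipartite_less_productive(
    params: PayoffParameters, coinf: CoinfectionParameters
) -> bool:
    """True when the multipartite endpoint (p=0, q=z=1/2) has lower mean
    fitness than the ancestral cooperator-only population, i.e. e < e**
    (strict; equality means equal productivity)."""
    ess = e_star_star(params, coinf)
    if ess is None:
        raise ValueError("productivity comparison undefined at beta = 0")
    return params.e < ess


def regime_grid(
    params_without_e: PayoffParameters,
    beta_axis,
    e_over_d_axis,
) -> RegimeGrid:
    """Classify every (beta, e/d) cell of a phase-diagram grid.

    The ``e`` field of ``params_without_e`` is ignored; each cell uses
    ``e = (e/d) * d``.  Axes must be sorted ascending.  The multipartite
    region's lower boundary traces e*(beta)/d.
    """
    beta_axis = np.asarray(beta_axis, dtype=float)
    e_axis = np.asarray(e_over_d_axis, dtype=float)
    if np.any(np.diff(beta_axis) < 0) or np.any(np.diff(e_axis) < 0):
        raise ValueError("grid axes must be sorted ascending")
    regime = np.empty((len(e_axis), len(beta_axis)), dtype=object)
    d = params_without_e.d
    for i, eod in enumerate(e_axis):
        p = params_without_e.with_e(eod * d)
        for j, beta in enumerate(beta_axis):
            regime[i, j] = classify_regime(p, CoinfectionParameters(beta=beta))
    return RegimeGrid(beta_axis, e_axis, regime)


def _is_stable(
    state: PopulationState,
    params: PayoffParameters,
    coinf: CoinfectionParameters,
    *,
    eps: float = 1e-4,
    steps: int = 5000,
    tol: float = 1e-6,
) -> bool:
    """Numerical stability check: perturb along simplex directions, iterate
    the replicator map, and ask whether the orbit returns to the point."""
    from .replicator import replicator_step

    x0 = state.as_array()
    directions = np.array(
        [[1.0, -1.0, 0.0], [1.0, 0.0, -1.0], [0.0, 1.0, -1.0]]
    )
    for sign in (1.0, -1.0):
        for v in directions:
            x = x0 + sign * eps * v
            if np.any(x < 0.0) or np.any(x > 1.0):
                continue  # perturbation leaves the simplex; skip direction
            s = PopulationState.from_array(x, clamp=True)
            for _ in range(steps):
                s = replicator_step(s, params, coinf)
            if np.max(np.abs(s.as_array() - x0)) > max(10.0 * eps, tol):
                return False
    return True
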