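"""Empirical parameterisation: linking measurable viral quantities to the
game parameters, and placing species on the (beta, e/d) phase plane.

Two conversions do the work:

* Coinfection.  Under Poisson infection with mean ``lam`` genomes per cell,
  the fraction of cells receiving two or more genomes is
  ``beta = 1 - exp(-lam) (1 + lam)``; half of cells are coinfected at an
  MOI of about 1.7.

* Single- vs double-infection advantage.  The particle:PFU ratio ``N``
  gives the probability ``x = 1 - 1/N`` that a particle is non-infectious;
  comparing the chance that at least one infectious particle reaches a cell
  hit by two particles versus one gives
  ``a/d = (1 - x) / (1 - x^2) = 1 / (1 + x)``, which lies in (0.5, 1].

Interference assays supply ``c/d`` directly (near zero for large-deletion /
defective-interfering cheats, substantially larger for point-mutant cheats).
With ``d`` normalised to 1, each species' e*(beta)/d curve determines the
minimum coinfection fraction at which genome fragmentation is predicted
without any group benefit (e/d <= 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import game

__all__ = [
    "EmpiricalEstimate",
    "SpeciesPlacement",
    "beta_from_moi",
    "moi_from_beta",
    "a_over_d_from_noninfectious",
    "noninfectious_from_particle_pfu",
    "beta_min_no_group_benefit",
    "place_species",
    "read_species_csv",
    "placements_to_frame",
]

logger = logging.getLogger(__name__)

SPECIES_CSV_COLUMNS = [
    "species",
    "cheat_class",
    "c_over_d",
    "particle_pfu",
    "noninfectious_prob",
    "source",
]


def beta_from_moi(lam):
    """Poisson probability that a cell receives >= 2 genomes at MOI ``lam``."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("moi must be >= 0")
    out = -np.expm1(-lam) - lam * np.exp(-lam)
    return float(out) if out.ndim == 0 else out


def moi_from_beta(beta: float) -> float:
    """Numerical inverse of :func:`beta_from_moi` on [0, 1)."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1); beta = 1 needs infinite MOI")
    if beta == 0.0:
        return 0.0
    hi = 1.0
    while beta_from_moi(hi) < beta:
        hi *= 2.0
    return float(brentq(lambda lam: beta_from_moi(lam) - beta, 0.0, hi, xtol=1e-12))


def a_over_d_from_noninfectious(x):
    """a/d = (1 - x)/(1 - x^2) where ``x`` is the probability a particle is
    non-infectious; algebraically 1/(1 + x), decreasing from 1 to 1/2."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise ValueError("noninfectious probability must lie in [0, 1)")
    out = (1.0 - x) / (1.0 - x**2)
    return float(out) if out.ndim == 0 else out


def noninfectious_from_particle_pfu(n):
    """Convert a raw particle:PFU ratio N >= 1 to the non-infectious
    probability x = 1 - 1/N."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("particle:PFU ratio must be >= 1")
    out = 1.0 - 1.0 / n
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EmpiricalEstimate:
    """Per-species measurements; exactly one of ``particle_pfu`` /
    ``noninfectious_prob`` must be supplied."""

    species: str
    c_over_d: float
    cheat_class: str = "large_deletion"
    particle_pfu: Optional[float] = None
    noninfectious_prob: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if (self.particle_pfu is None) == (self.noninfectious_prob is None):
            raise ValueError(
                "supply exactly one of particle_pfu, noninfectious_prob"
            )
        if self.c_over_d < 0:
            raise ValueError("c_over_d must be >= 0")

    @property
    def x(self) -> float:
        """Non-infectious probability, whichever way it was supplied."""
        if self.noninfectious_prob is not None:
            if not 0.0 <= self.noninfectious_prob < 1.0:
                raise ValueError("noninfectious_prob must lie in [0, 1)")
            return self.noninfectious_prob
        return noninfectious_from_particle_pfu(self.particle_pfu)

    @property
    def a_over_d(self) -> float:
        return a_over_d_from_noninfectious(self.x)


@dataclass(frozen=True)
class SpeciesPlacement:
    """A species' position on the phase plane: its a/d estimate, the e*/d
    curve over a beta grid, and the minimal beta at which fragmentation is
    predicted with no group benefit (``None`` when e*/d stays above 1 for
    all beta, i.e. a group benefit is required)."""

    species: str
    a_over_d: float
    c_over_d: float
    beta_min: Optional[float]
    beta_grid: np.ndarray
    e_star_over_d: np.ndarray


def beta_min_no_group_benefit(a_over_d: float, c_over_d: float) -> Optional[float]:
    """Smallest beta with e*(beta) <= d, i.e. 2a / (2a - 2c + d) with d = 1;
    defined only when 2c <= d (weakly interfering cheats never qualify)."""
    a, c = a_over_d, c_over_d
    if 2.0 * c > 1.0:
        return None
    bmin = 2.0 * a / (2.0 * a - 2.0 * c + 1.0)
    return bmin if bmin <= 1.0 else None


def place_species(
    estimate: EmpiricalEstimate,
    beta_grid=None,
    *,
    b_over_d: float = 10.0,
) -> SpeciesPlacement:
    """Compute the e*/d phase boundary for one species (d normalised to 1).

    ``b_over_d`` only affects payoff construction, not the e* curve; the
    default reflects the strong competitive advantage of deletion cheats.
    """
    if beta_grid is None:
        beta_grid = np.linspace(0.01, 1.0, 100)
    beta_grid = np.asarray(beta_grid, dtype=float)
    a = estimate.a_over_d
    c = estimate.c_over_d
    # e* only involves a and c; keep c below a to satisfy payoff ordering,
    # clamping pathological c/d >= a/d estimates just for curve evaluation.
    c_eff = min(c, a * (1.0 - 1e-9))
    c_eff = max(c_eff, 1e-12)
    params = game.PayoffParameters(a=a, b=b_over_d, c=c_eff, d=1.0, e=1.0)
    curve = np.array(
        [
            game.e_star(params, game.CoinfectionParameters(beta=b))
            for b in beta_grid
        ]
    )
    return SpeciesPlacement(
        species=estimate.species,
        a_over_d=a,
        c_over_d=c,
        beta_min=beta_min_no_group_benefit(a, c),
        beta_grid=beta_grid,
        e_star_over_d=curve,
    )


def read_species_csv(path) -> list[EmpiricalEstimate]:
    """Read a species-estimates table (see ``SPECIES_CSV_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = {"species", "c_over_d"} - set(df.columns)
    if missing:
        raise ValueError(f"species CSV missing columns: {sorted(missing)}")
    estimates = []
    for _, row in df.iterrows():
        pfu = row.get("particle_pfu")
        xni = row.get("noninfectious_prob")
        estimates.append(
            EmpiricalEstimate(
                species=str(row["species"]),
                c_over_d=float(row["c_over_d"]),
                cheat_class=str(row.get("cheat_class", "large_deletion")),
                particle_pfu=None if pd.isna(pfu) else float(pfu),
                noninfectious_prob=None if pd.isna(xni) else float(xni),
                source=str(row.get("source", "")),
            )
        )
    return estimates


def placements_to_frame(placements: list[SpeciesPlacement]) -> pd.DataFrame:
    """One summary row per species (curves are kept on the objects)."""
    return pd.DataFrame(
        {
            "species": [p.species for p in placements],
            "a_over_d": [p.a_over_d for p in placements],
            "c_over_d": [p.c_over_d for p in placements],
            "beta_min_no_group_benefit": [
                np.nan if p.beta_min is None else p.beta_min for p in placements
            ],
            "requires_group_benefit": [p.beta_min is None for p in placements],
        }
    )
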