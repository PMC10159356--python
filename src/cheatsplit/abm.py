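"""Agent-based simulation of genome fragmentation over all partial-genome
strategies.

A viral genome carries up to G genes; every subset of genes is a strategy,
encoded as a bit vector (all ones = full-length cooperator, all zeros =
"full cheat").  Each generation:

1. every one of a finite number of host cells receives k genomes, with
   k ~ Poisson(lambda) and genomes drawn from the population frequencies;
2. a cell is productive only if every gene is present at least once; its
   productivity is S**gamma where S is the number of complete gene sets
   (the minimum per-gene copy count), multiplied by the group-benefit
   factor e when the cell was completed purely by complementation (no
   full-length genome present);
3. the cell's productivity is divided among its genomes in proportion to
   copy number times a competitive weight w(g) = 1 + y (1 - g/G)**alpha
   that favours shorter genomes (full cheat 1 + y, cooperator exactly 1);
4. next-generation frequencies are the normalised summed shares, after
   which a fraction ``mut_rate`` of every strategy mutates, spread evenly
   over the 2**G - 1 other strategies (cooperators can re-arise from
   cheats).

The run is classified by which strategies persist above five times the
mutation rate: a monopartite outcome (cooperator persists), a multipartite/
segmented outcome (cooperator extinct, a complementary set of partial
cheats covers every gene), or an unclassifiable/extinct population.

A packaging extension (G = 2 only) draws virions instead of genomes: a
fraction ``prop_single`` of virions carry one genome, the rest carry two
genomes copackaged unselectively within the same length class (the
full-length genome fills a capsid on its own).  A ``pairwise`` coinfection
mode, in which cells receive exactly one or two genomes with probability
1 - beta / beta, mirrors the analytic game for cross-validation.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "SimConfig",
    "SimResult",
    "OutcomeClass",
    "CellContents",
    "enumerate_strategies",
    "strategy_bits",
    "gene_counts",
    "competitive_weight",
    "sample_cell_contents",
    "package_and_infect",
    "cell_productivity",
    "allocate_progeny",
    "apply_mutation",
    "generation",
    "run",
    "classify_outcome",
    "run_replicates",
    "sweep",
]

logger = logging.getLogger(__name__)

MAX_GENES = 8
_EXTINCTION_FACTOR = 5.0  # persistence cut-off = 5 x mut_rate


@dataclass(frozen=True)
class Genotype:
    """One strategy: an ordered gene-presence bit vector."""

    gene_presence: tuple[int, ...]

    @property
    def gene_count(self) -> int:
        return sum(self.gene_presence)

    @property
    def bits(self) -> str:
        return "".join(str(b) for b in self.gene_presence)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.bits


def enumerate_strategies(n_genes: int) -> list[Genotype]:
    """All 2**G strategies in binary-ascending order; index 0 is the full
    cheat, index 2**G - 1 the cooperator."""
    if not 1 <= n_genes <= MAX_GENES:
        raise ValueError(f"n_genes must lie in [1, {MAX_GENES}], got {n_genes}")
    return [
        Genotype(tuple(int(ch) for ch in format(i, f"0{n_genes}b")))
        for i in range(2**n_genes)
    ]


@functools.cache
def strategy_bits(n_genes: int) -> np.ndarray:
    """(2**G, G) presence matrix in the same order as enumerate_strategies."""
    idx = np.arange(2**n_genes, dtype=np.uint32)
    shifts = np.arange(n_genes - 1, -1, -1, dtype=np.uint32)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(float)


@functools.cache
def gene_counts(n_genes: int) -> np.ndarray:
    return strategy_bits(n_genes).sum(axis=1)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulation run.

    ``e`` is the group-benefit multiplier for cells completed purely by
    complementation (1 = no group benefit); ``y`` scales the competitive
    advantage of shorter genomes (full cheat is 1 + y times as competitive
    as a cooperator); ``alpha`` shapes that advantage (< 1 decelerating,
    > 1 accelerating); ``gamma`` scales productivity with the number of
    complete gene sets.  ``prop_single`` switches on the virion-packaging
    extension (G = 2 only); ``coinfection="pairwise"`` replaces Poisson
    infection by the analytic 1-or-2-genomes model with probability
    ``beta`` of a double infection.
    """

    n_genes: int = 2
    moi: float = 5.0
    n_cells: int = 2000
    n_generations: int = 2000
    mut_rate: float = 1e-4
    e: float = 1.0
    y: float = 99.0
    alpha: float = 1.0
    gamma: float = 1.0
    prop_single: Optional[float] = None
    coinfection: str = "poisson"
    beta: Optional[float] = None
    seed: Optional[int] = None
    record_every: int = 10
    initial_freqs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_genes <= MAX_GENES:
            raise ValueError(f"n_genes must lie in [1, {MAX_GENES}]")
        if self.moi < 0:
            raise ValueError("moi must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 <= self.mut_rate < 1.0:
            raise ValueError("mut_rate must lie in [0, 1)")
        if self.e < 0:
            raise ValueError("e must be >= 0")
        if self.y < 0:
            raise ValueError("y must be >= 0")
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be positive")
        if self.prop_single is not None:
            if not 0.0 <= self.prop_single <= 1.0:
                raise ValueError("prop_single must lie in [0, 1]")
            if self.n_genes != 2:
                raise ValueError("packaging mode requires n_genes = 2")
        if self.coinfection not in ("poisson", "pairwise"):
            raise ValueError("coinfection must be 'poisson' or 'pairwise'")
        if self.coinfection == "pairwise":
            if self.beta is None or not 0.0 <= self.beta <= 1.0:
                raise ValueError("pairwise coinfection requires beta in [0, 1]")
            if self.prop_single is not None:
                raise ValueError("packaging mode is Poisson-only")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.initial_freqs is not None:
            f = np.asarray(self.initial_freqs, dtype=float)
            if f.shape != (2**self.n_genes,):
                raise ValueError("initial_freqs must have length 2**n_genes")
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("initial_freqs must be a frequency vector")

    @property
    def n_strategies(self) -> int:
        return 2**self.n_genes

    @property
    def persistence_threshold(self) -> float:
        return max(_EXTINCTION_FACTOR * self.mut_rate, 1e-9)


@dataclass(frozen=True)
class OutcomeClass:
    """Classification of a finished run (see module docstring)."""

    cooperator_extinct: bool
    n_segments: Optional[int]
    persisting_set: tuple[str, ...]
    evenness: Optional[float]
    full_cheat_load: float
    label: str  # monopartite | multipartite | unclassifiable | extinct


@dataclass
class SimResult:
    config: SimConfig
    generations: np.ndarray
    trajectory: np.ndarray  # (n_recorded, n_strategies)
    final_freqs: np.ndarray
    extinct: bool
    outcome: Optional[OutcomeClass] = None


@dataclass(frozen=True)
class CellContents:
    """Sparse per-cell genome lists: parallel arrays of cell index and
    strategy index, one entry per genome."""

    n_cells: int
    n_strategies: int
    cells: np.ndarray
    strategies: np.ndarray

    def counts(self) -> np.ndarray:
        """Dense (n_cells, n_strategies) genotype count table."""
        table = np.zeros((self.n_cells, self.n_strategies), dtype=np.int64)
        np.add.at(table, (self.cells, self.strategies), 1)
        return table


def competitive_weight(gene_count, config: SimConfig):
    """w(g) = 1 + y (1 - g/G)**alpha; 1 for the cooperator, 1 + y for the
    full cheat, strictly decreasing in encoded gene number for y > 0."""
    g = np.asarray(gene_count, dtype=float)
    out = 1.0 + config.y * (1.0 - g / config.n_genes) ** config.alpha
    return float(out) if out.ndim == 0 else out


def _draw_strategies(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(freqs)
    cdf[-1] = 1.0  # guard against rounding at the top
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.int64)


def sample_cell_contents(
    freqs: np.ndarray, n_cells: int, lam: float, rng: np.random.Generator
) -> CellContents:
    """Poisson(lambda) genomes per cell, drawn with replacement from the
    population frequencies (the pool is treated as effectively infinite)."""
    freqs = np.asarray(freqs, dtype=float)
    k = rng.poisson(lam, n_cells)
    cells = np.repeat(np.arange(n_cells, dtype=np.int64), k)
    strategies = _draw_strategies(freqs, int(k.sum()), rng)
    return CellContents(n_cells, len(freqs), cells, strategies)


def _pairwise_contents(
    freqs: np.ndarray, n_cells: int, beta: float, rng: np.random.Generator
) -> CellContents:
    """Analytic-model coinfection: every cell gets one genome, a fraction
    beta of cells a second one (validation mode)."""
    freqs = np.asarray(freqs, dtype=float)
    k = 1 + (rng.random(n_cells) < beta).astype(np.int64)
    cells = np.repeat(np.arange(n_cells, dtype=np.int64), k)
    strategies = _draw_strategies(freqs, int(k.sum()), rng)
    return CellContents(n_cells, len(freqs), cells, strategies)


def package_and_infect(
    freqs: np.ndarray,
    n_cells: int,
    lam: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> CellContents:
    """Virion-packaging infection (G = 2): cells receive Poisson(lambda)
    virions; each virion holds one genome with probability ``prop_single``,
    otherwise two genomes copackaged unselectively within the same length
    class (only sub-full-length genomes can share a capsid)."""
    if config.n_genes != 2:
        raise ValueError("packaging mode requires n_genes = 2")
    freqs = np.asarray(freqs, dtype=float)
    prop_single = config.prop_single if config.prop_single is not None else 1.0
    k = rng.poisson(lam, n_cells)
    n_virions = int(k.sum())
    vcells = np.repeat(np.arange(n_cells, dtype=np.int64), k)
    single = rng.random(n_virions) < prop_single

    counts = gene_counts(config.n_genes)
    cheat_mask = counts < config.n_genes
    cheat_freqs = freqs * cheat_mask
    cheat_total = cheat_freqs.sum()
    if cheat_total <= 0.0 and not single.all():
        # Two-genome virions cannot be filled from a cooperator-only pool.
        n_fallback = int((~single).sum())
        logger.info(
            "no sub-full-length genomes available; %d two-genome virions "
            "fell back to single-genome packaging",
            n_fallback,
        )
        single[:] = True

    out_cells = [vcells[single]]
    out_strats = [_draw_strategies(freqs, int(single.sum()), rng)]

    n_double = int((~single).sum())
    if n_double:
        first = _draw_strategies(cheat_freqs / cheat_total, n_double, rng)
        second = np.empty(n_double, dtype=np.int64)
        for length in np.unique(counts[first]):
            sel = counts[first] == length
            class_freqs = freqs * (counts == length)
            total = class_freqs.sum()
            if total <= 0.0:  # pragma: no cover - first draw guarantees mass
                second[sel] = first[sel]
                continue
            second[sel] = _draw_strategies(class_freqs / total, int(sel.sum()), rng)
        dcells = vcells[~single]
        out_cells += [dcells, dcells]
        out_strats += [first, second]

    cells = np.concatenate(out_cells)
    strategies = np.concatenate(out_strats)
    order = np.argsort(cells, kind="stable")
    return CellContents(n_cells, len(freqs), cells[order], strategies[order])


def _infect(freqs: np.ndarray, config: SimConfig, rng: np.random.Generator) -> CellContents:
    if config.coinfection == "pairwise":
        return _pairwise_contents(freqs, config.n_cells, config.beta, rng)
    if config.prop_single is not None:
        return package_and_infect(freqs, config.n_cells, config.moi, config, rng)
    return sample_cell_contents(freqs, config.n_cells, config.moi, rng)


def _cell_productivities(contents: CellContents, config: SimConfig) -> np.ndarray:
    """Vectorised per-cell productivity (0 for cells missing any gene)."""
    bits = strategy_bits(config.n_genes)
    n_cells = contents.n_cells
    sets = None
    for j in range(config.n_genes):
        cnt = np.bincount(
            contents.cells, weights=bits[contents.strategies, j], minlength=n_cells
        )
        sets = cnt if sets is None else np.minimum(sets, cnt)
    complete = sets > 0
    prod = np.where(complete, sets, 0.0) ** config.gamma * complete
    coop = config.n_strategies - 1
    has_coop = (
        np.bincount(
            contents.cells,
            weights=(contents.strategies == coop).astype(float),
            minlength=n_cells,
        )
        > 0
    )
    return np.where(complete & ~has_coop, prod * config.e, prod)


def cell_productivity(cell_strategies: Sequence[int], config: SimConfig) -> float:
    """Productivity of a single cell given its genome strategy indices."""
    strategies = np.asarray(cell_strategies, dtype=np.int64)
    contents = CellContents(
        1, config.n_strategies, np.zeros(len(strategies), dtype=np.int64), strategies
    )
    return float(_cell_productivities(contents, config)[0])


def allocate_progeny(cell_strategies: Sequence[int], config: SimConfig) -> np.ndarray:
    """Split one cell's productivity across strategies in proportion to copy
    number times competitive weight; allocations sum to the productivity."""
    strategies = np.asarray(cell_strategies, dtype=np.int64)
    prod = cell_productivity(strategies, config)
    out = np.zeros(config.n_strategies)
    if prod == 0.0 or len(strategies) == 0:
        return out
    w = competitive_weight(gene_counts(config.n_genes), config)[strategies]
    shares = prod * w / w.sum()
    np.add.at(out, strategies, shares)
    return out


def apply_mutation(freqs: np.ndarray, mut_rate: float) -> np.ndarray:
    """Each strategy keeps (1 - mut_rate) of its mass; the rest is spread
    evenly over the other strategies.  Exactly mass-conserving."""
    freqs = np.asarray(freqs, dtype=float)
    if mut_rate == 0.0 or len(freqs) == 1:
        return freqs.copy()
    lost = freqs * mut_rate
    return freqs - lost + (lost.sum() - lost) / (len(freqs) - 1)


def generation(
    freqs: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One full life cycle; returns (next frequencies, whole-population
    extinction flag).  Extinction is flagged, not raised."""
    contents = _infect(freqs, config, rng)
    if contents.cells.size == 0:
        return freqs.copy(), True
    prod = _cell_productivities(contents, config)
    w = competitive_weight(gene_counts(config.n_genes), config)[contents.strategies]
    cell_w = np.bincount(contents.cells, weights=w, minlength=contents.n_cells)
    shares = prod[contents.cells] * w / cell_w[contents.cells]
    progeny = np.bincount(
        contents.strategies, weights=shares, minlength=config.n_strategies
    )
    total = progeny.sum()
    if total <= 0.0:
        return freqs.copy(), True
    return apply_mutation(progeny / total, config.mut_rate), False


def _initial_freqs(config: SimConfig) -> np.ndarray:
    if config.initial_freqs is not None:
        return np.asarray(config.initial_freqs, dtype=float)
    f = np.zeros(config.n_strategies)
    f[-1] = 1.0  # ancestral population: pure cooperator
    return f


def run(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimResult:
    """Run one simulation, recording the trajectory every ``record_every``
    generations; bit-reproducible from the seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freqs = _initial_freqs(config)
    recorded = [freqs.copy()]
    gens = [0]
    extinct = False
    for t in range(1, config.n_generations + 1):
        freqs, dead = generation(freqs, config, rng)
        if dead:
            extinct = True
            break
        if t % config.record_every == 0 or t == config.n_generations:
            recorded.append(freqs.copy())
            gens.append(t)
    result = SimResult(
        config=config,
        generations=np.array(gens),
        trajectory=np.array(recorded),
        final_freqs=freqs,
        extinct=extinct,
    )
    result.outcome = classify_outcome(result, config)
    return result


def classify_outcome(result: SimResult, config: SimConfig) -> OutcomeClass:
    """Apply the persistence rules to a finished run's final frequencies."""
    freqs = result.final_freqs
    thr = config.persistence_threshold
    counts = gene_counts(config.n_genes)
    coop = config.n_strategies - 1
    cooperator_extinct = bool(freqs[coop] < thr)
    full_cheat_load = float(freqs[0]) if config.n_genes >= 1 else 0.0
    persisting_idx = np.flatnonzero(freqs > thr)
    persisting = tuple(format(i, f"0{config.n_genes}b") for i in persisting_idx)

    if result.extinct:
        return OutcomeClass(True, None, persisting, None, full_cheat_load, "extinct")
    if not cooperator_extinct:
        return OutcomeClass(False, 1, persisting, None, full_cheat_load, "monopartite")

    partial = persisting_idx[(counts[persisting_idx] > 0) & (persisting_idx != coop)]
    bits = strategy_bits(config.n_genes)
    covered = bool(len(partial)) and bool(bits[partial].max(axis=0).min() > 0)
    if not covered:
        return OutcomeClass(
            True, None, persisting, None, full_cheat_load, "unclassifiable"
        )
    seg_counts = counts[partial]
    evenness = float(seg_counts.min() / seg_counts.max())
    return OutcomeClass(
        True, int(len(partial)), persisting, evenness, full_cheat_load, "multipartite"
    )


def pairwise_effective_payoffs(config: SimConfig):
    """Map a G = 2 configuration onto the analytic game's payoffs under the
    ``pairwise`` coinfection model (cells hold exactly one or two genomes).

    Reading the within-cell rules off two-genome cells, with the lone-
    cooperator payoff as the unit: a = 1; d = 2**(gamma - 1) (two complete
    sets shared between two cooperators); a cooperator+cheat cell has a
    single complete set, so b = w1/(w1 + 1) and c = 1/(w1 + 1) with
    w1 = 1 + y (1/2)**alpha; and each of two complementing cheats earns
    e_sim/2.  Note b < 1 <= d always: under strictly pairwise infection the
    simulator's proportional-share rule cannot hand a cheat more than a
    cooperator pair earns, so cheat invasion in the Poisson simulator is
    driven by cells holding three or more genomes.  The mapping is exact for
    the pairwise validation mode and is used to cross-check regime
    predictions against :func:`cheatsplit.game.classify_regime`.
    """
    from .game import PayoffParameters

    if config.n_genes != 2:
        raise ValueError("effective payoffs are defined for n_genes = 2")
    w1 = float(competitive_weight(1, config))
    return PayoffParameters(
        a=1.0,
        b=w1 / (w1 + 1.0),
        c=1.0 / (w1 + 1.0),
        d=2.0 ** (config.gamma - 1.0),
        e=config.e / 2.0,
    )


def run_replicates(
    config: SimConfig, n_replicates: int, master_seed: int
) -> pd.DataFrame:
    """Independent replicate runs from spawned RNG streams; one row per run
    with the outcome fields."""
    streams = np.random.SeedSequence(master_seed).spawn(n_replicates)
    rows = []
    for i, ss in enumerate(streams):
        res = run(config, rng=np.random.default_rng(ss))
        o = res.outcome
        rows.append(
            {
                "replicate": i,
                "label": o.label,
                "cooperator_extinct": o.cooperator_extinct,
                "n_segments": o.n_segments,
                "evenness": o.evenness,
                "full_cheat_load": o.full_cheat_load,
                "extinct_population": res.extinct,
            }
        )
    return pd.DataFrame(rows)


def fragmented(df: pd.DataFrame) -> pd.Series:
    """Boolean per-run indicator of genome fragmentation: the cooperator is
    extinct and a complementary set of partial cheats persists."""
    return (df["label"] == "multipartite") & (df["n_segments"] >= 2)


def sweep(
    configs: Sequence[SimConfig], n_replicates: int, master_seed: int = 0
) -> pd.DataFrame:
    """Replicated outcomes over a configuration grid.

    Returns one row per (configuration, outcome class) with the fraction of
    replicates; the ``outcome`` key is ``monopartite``/``extinct``/
    ``unclassifiable`` or ``k_segments`` for multipartite endpoints.
    """
    seeds = np.random.SeedSequence(master_seed).spawn(len(configs))
    rows = []
    for ci, (config, ss) in enumerate(zip(configs, seeds)):
        sub_seed = int(ss.generate_state(1)[0] % 2**31)
        df = run_replicates(config, n_replicates, sub_seed)
        outcome = df.apply(
            lambda r: f"{int(r.n_segments)}_segments"
            if r.label == "multipartite"
            else r.label,
            axis=1,
        )
        frac = outcome.value_counts(normalize=True)
        for name, f in frac.items():
            rows.append(
                {
                    "config_index": ci,
                    "n_genes": config.n_genes,
                    "moi": config.moi,
                    "e": config.e,
                    "alpha": config.alpha,
                    "prop_single": config.prop_single,
                    "outcome": name,
                    "fraction": float(f),
                    "n_replicates": n_replicates,
                }
            )
    return pd.DataFrame(rows)
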