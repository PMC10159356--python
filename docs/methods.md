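# Methods

`cheatsplit` models how intragenomic cheating can drive the evolution of
multipartite viruses (genome segments packaged and transmitted in separate
capsids) and segmented viruses (segments co-packaged in one capsid).  The
question it formalises: when can partial genomes that skip producing shared
gene products — the viral cheats exemplified by defective interfering (DI)
genomes — invade a full-length "cooperator" population and, by
complementing one another in coinfected cells, replace it entirely?

## The analytic game

Host cells receive one viral genome with probability `1 − β` and two with
probability `β`.  Three strategies compete: the cooperator `C` encoding
both of two shared gene products, and cheats `D1`, `D2` each lacking a
different one.  Payoffs (expected progeny): a lone cooperator earns `a`;
two cooperators earn `d` each; in a mixed cell the cooperator earns `c`
and the cheat `b`; two complementary cheats earn `e` each; identical
cheats, or a lone cheat, earn nothing.  Parameter constraints:
`d ≥ a > c > 0`, `b > 0`, `e ≥ 0`.  Mean fitnesses at frequencies
`(p, q, z)`:

    W(C)  = a(1 − β) + β(cq + cz + dp)
    W(D1) = β(bp + ez)
    W(D2) = β(bp + eq)

At `β = 1` with one cheat type this is the Hawk–Dove / Snowdrift game.

Closed forms implemented in `cheatsplit.game` and verified against the
replicator oracle:

* cheat invasion requires `b > d` and `β > a/(a + b − d)`;
* cooperator/single-cheat equilibrium `p* = (a − aβ + cβ)/(β(b + c − d))`;
* two-cheat equilibrium `q* = z* = (a − (a + b − d)β)/((e − 2(b + c − d))β)`,
  `p* = 1 − 2q*`; when the interior `p*` crosses zero the population is at
  the multipartite boundary `p = 0, q = z = 1/2`;
* cooperator extinction (multipartitism) requires
  `e ≥ e* = (2a − 2aβ + 2cβ)/β`;
* the multipartite population is *less productive* than its monopartite
  ancestor whenever `e < e** = 2(d + a(−1 + 1/β))`.

Because `e** − e* = 2(d − c) > 0` identically, a window `e* < e < e**`
always exists: multipartitism can evolve while *lowering* mean population
fitness — no group benefit is required.  With fully interfering cheats
(`c → 0`), `a = d/2` and no group benefit (`e = d`), the multipartite
region opens at exactly `β = 0.5`, i.e. a Poisson MOI of about 1.7.

Boundary conventions: `e = e*` counts as multipartite (the closed form is
an inequality that includes equality); `e = e**` counts as *not* less
productive (strict inequality).  Degenerate denominators
(`b + c − d = 0`, `e = 2(b + c − d)`) raise explicit errors rather than
returning infinities.  Equilibria computed outside the simplex are clamped
to the nearest boundary and relabelled; this is precisely the extinction
argument behind `e*`.  The alternative complementation-driven route to
joint cheat invasion with `b < d` (needing `e > b`) is flagged by
`classify_regime` but deliberately not analysed further; it is a
bistability not reachable from rare mutants.

## The replicator oracle

`cheatsplit.replicator` iterates the multiplicative (discrete-time)
replicator map `x_i ← x_i W_i / W̄`, which shares fixed points with the
continuous-time dynamics while matching a generational viral life cycle
and requiring no integrator.  It serves as an independent numerical check
on every closed form: fixed-point residuals at the analytic equilibria
must vanish to rounding error, and regime labels must match iteration
from a cooperator-resident state with both cheats introduced at `1e−6`
(rare enough to approximate invasion analysis, large enough for double
precision).  Exactly at the thresholds the map's contraction rate
approaches one and finite iteration cannot classify, so sweep comparisons
exclude draws within 5% of a boundary; the fixed-point check needs no
such margin.  Stability is assessed numerically by perturbing an
equilibrium along simplex directions and iterating; no analytic Jacobian
is reported.

## The agent-based simulation

`cheatsplit.abm` drops the two-genomes-per-cell and two-gene restrictions.
A genome carries up to `G ≤ 8` genes; every subset is a strategy (all-ones
cooperator … all-zeros "full cheat").  Each generation a finite number of
cells receives `k ~ Poisson(λ)` genomes drawn from the population
frequencies (the genome pool itself is treated as effectively infinite;
the finite element is the cell count).  Within-cell rules:

* a cell missing any gene is unproductive;
* otherwise productivity is `S^γ`, where `S` is the number of complete
  gene sets (the minimum per-gene copy count); `γ = 1` by default — the
  simplest monotone version of productivity increasing with each
  additional set;
* cells completed purely by complementation (no full-length genome
  present) are additionally scaled by the group-benefit factor `e`
  (`e = 1`: complementation-completed cells are exactly as productive as
  cooperator-completed ones; the analytic payoff `e` plays the same role
  for `D1 + D2` cells).  Cells containing a cooperator use the baseline —
  the mixed-cell rule is a modelling choice, documented here;
* the cell's productivity is split among its genomes in proportion to
  copy number times a competitive weight `w(g) = 1 + y(1 − g/G)^α`:
  shorter genomes replicate disproportionately, the cooperator has weight
  exactly 1 and the full cheat `1 + y`.  `α < 1` makes the advantage
  decelerating in the number of genes shed, `α > 1` accelerating;
* next-generation frequencies are the normalised summed shares, after
  which a fraction `mut_rate` of every strategy mutates, spread evenly
  over all other strategies — cooperators can re-evolve from cheats, a
  conservative choice that works against multipartitism.

A run is classified from its final frequencies: strategies above five
times the mutation rate persist; the cooperator is extinct below that
cut; a multipartite/segmented outcome requires the persisting partial
cheats to jointly cover every gene, and the number of segments is the
size of that persisting set (overlapping sets are counted at face value
and are visible through the reported set itself).  Evenness is the
min/max gene count over the persisting partial strategies.  If the
cooperator is extinct but coverage fails the run is unclassifiable; if
nothing reproduces the whole population is extinct.

### Defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| `n_cells` | 2,000 | finite-cell sampling is the only stochasticity; at 2,000 cells outcome fractions are stable while full sweeps stay tractable on one core |
| `n_generations` | 2,000 | the segment-count distribution under the defaults is stationary between 2,000 and 5,000 generations (checked directly) |
| `mut_rate` | 1e−4 | keeps all strategies in the mutation–selection balance well below the 5× extinction cut |
| `e` | 1.0 | no group benefit — the null condition of interest |
| `y` | 99 | a full cheat is 100× as competitive as a cooperator; DI genomes are reported to reach competitive advantages of orders of magnitude (up to ~10⁴×), and 10× proved too weak to reproduce the documented segment distributions, while ~10⁴× tips populations into full-cheat-dominated collapse |
| `α`, `γ` | 1.0 | linear advantage shape and linear productivity in complete sets; both exposed as dials |
| `record_every` | 10 | trajectory thinning |

The functional forms for the competitive weight and the productivity are
modelling choices: only the directions (shorter genomes more competitive;
productivity non-decreasing in complete sets; magnitude controlled by `y`)
are pinned down by the biology.

### Packaging extension

To model segmented viruses, cells receive `k ~ Poisson(λ)` *virions*
instead of genomes (restricted to `G = 2` for tractability).  A fraction
`prop_single` of virions carry one genome drawn from the population; the
rest carry two genomes, copackaged unselectively within the same length
class — a full-length genome fills a capsid on its own and never shares.
If the pool holds no sub-full-length genomes, unfillable two-genome
virions fall back to single-genome packaging (logged); this corner only
arises in a pure-cooperator population.  Copackaging raises the genome
MOI above the particle MOI, so fragmentation evolves at lower particle
MOI when `prop_single = 0` — the segmented-virus prediction.

### Validation against the analytic game

Under the simulator's own within-cell rules, a pairwise
(two-genomes-per-cell) world can never hand a cheat more than a
cooperator pair earns (`b = w₁/(w₁+1) < 1 ≤ d`): cheat invasion in the
Poisson simulator is driven by cells with three or more genomes, which
the three-strategy game deliberately omits.  A literal payoff-matched
regime comparison across the board is therefore impossible for structural
reasons, and the two levels are expected to agree only broadly.  The
implementable faithful check is the `coinfection="pairwise"` mode, which
reproduces the analytic infection process exactly: there the simulator
(i) never shows cheat invasion from rare, matching `b < d`, and (ii)
started at the multipartite boundary state, remains multipartite exactly
when the mapped complementation payoff `e_sim/2` clears the analytic
threshold `e*` — a sharp, parameter-dependent prediction tested across
`(β, e)` combinations (`abm.pairwise_effective_payoffs` documents the
mapping).

## Empirical parameterisation

`cheatsplit.empirical` links measurable quantities to the phase plane:
`β = 1 − e^{−λ}(1 + λ)` converts a Poisson MOI to a coinfection fraction
(numerically inverted for the reverse); a particle:PFU ratio `N ≥ 1`
gives the non-infectious probability `x = 1 − 1/N`, and comparing the
chance that at least one infectious particle reaches a doubly- versus
singly-hit cell gives `a/d = (1 − x)/(1 − x²) = 1/(1 + x) ∈ (0.5, 1]`.
Interference assays supply `c/d` directly.  With `d` normalised to 1, a
species' minimum coinfection fraction for fragmentation with no group
benefit is `β_min = 2a/(2a − 2c + d)`, defined only when `2c ≤ d`:
weakly interfering cheats (point mutants, `c/d` large) require a group
benefit at every coinfection level.  The `β` here is the unconditional
probability of receiving ≥ 2 genomes — the definition under which the
printed MOI ≈ 1.7 ↔ β = 0.5 correspondence holds.  Species estimates are
consumed from user CSVs; the shipped table is a synthetic illustration of
the two cheat classes, not measured data.

## Comparative summaries

`cheatsplit.comparative` reduces a genus-level table (realm, produces-DI
flag, multipartite flag) to per-realm fractions and reports Spearman and
Pearson correlations across realms.  With a handful of realms — each
treated as an independent origin of viruses — significance testing is
meaningless and deliberately omitted.  The literature collation that
produces a real genus table is outside this package; the shipped fixture
is synthetic with a built-in positive association.

## What the synthetic experiments do and do not show

All simulation results in the test-suite and acceptance script are
generated by this package's own generator under the documented defaults;
they probe internal consistency (simulator ↔ analytic model) and the
qualitative mechanisms (coinfection, complementation, competition shape,
copackaging, genome size, group benefits), at problem sizes of 1,000–
2,000 cells, 800–2,000 generations and 15–100 replicates per condition.
They do not calibrate to any particular virus: real infections add
spatial structure, within-cell replication kinetics, nucleotide-level
mutation, selective packaging and fluctuating MOI, none of which are
modelled.  Where outcome statistics are compared across conditions the
tests use three-standard-error separations on replicate fractions; the
fragmentation-versus-full-cheat-load association is computed within each
MOI level, because coinfection intensity raises both quantities and the
pooled correlation would confound the within-population effect.

## Known limitations

* Stability is established numerically, not via eigenvalue analysis.
* The simulator's competitive-weight and productivity functions are
  parametric stand-ins for unknown mechanistic forms; conclusions that
  depend on their curvature (the `α` comparisons) should be read as
  qualitative.
* The packaging extension allows at most two genomes per virion and two
  genes.
* Genus-level comparative inputs must be supplied by the user for any
  real inference; the fixture only exercises the computation.
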