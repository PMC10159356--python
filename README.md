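# cheatsplit

Why would a virus split its genome across several capsids, when an
infection then only succeeds if every segment happens to reach the same
cell?  `cheatsplit` implements a two-level model in which this costly
**multipartite** organisation — and its co-packaged cousin, the
**segmented** genome — emerges from within-genome conflict: *cheats* that
drop a shared gene product (as defective interfering genomes do) invade a
full-length "cooperator" population, complement one another in coinfected
cells, and drive the cooperator extinct.  No group-level benefit to being
multipartite is required; the transition can even lower the productivity
of the whole population.

The package is aimed at evolutionary virologists and social-evolution
theorists who want to explore, parameterise or extend the model.

## The model in brief

Cells are infected by one genome with probability `1 − β`, two with
probability `β`.  A cooperator `C` competes with two complementing cheats
`D1`, `D2` with fitnesses

    W(C)  = a(1 − β) + β(cq + cz + dp)
    W(D1) = β(bp + ez)
    W(D2) = β(bp + eq)

(payoffs `d ≥ a > c > 0`, `b > 0`, `e ≥ 0`; frequencies `p + q + z = 1`).
Cheats invade when `b > d` and `β > a/(a + b − d)`; they *replace* the
cooperator — the multipartite transition — when complementation clears

    e ≥ e* = (2a − 2aβ + 2cβ)/β ,

and the resulting multipartite population is less productive than its
ancestor whenever `e < e** = 2(d + a(−1 + 1/β))`.  Since
`e** − e* = 2(d − c) > 0`, a window always exists in which multipartitism
evolves *and* lowers group productivity.  An agent-based simulator
generalises this to up to 8 genes, all 2^G partial-genome strategies,
Poisson coinfection, within-cell competition favouring shorter genomes,
mutation, and virion co-packaging (the segmented-virus case).

## Worked example

Thresholds and equilibria for a strongly interfering cheat
(`a=1, b=2, c=0.2, d=1, e=1`) at 80% coinfection:

```bash
$ cheatsplit equilibria --a 1 --b 2 --c 0.2 --d 1 --e 1 --beta 0.8 --numeric
```

prints (abridged):

```
beta_invasion = 0.5
e_star = 0.8999999999999999
e_star_star = 2.5
regime = multipartite
two_cheat_p = 0.0
two_cheat_q = 0.5
two_cheat_z = 0.5
oracle_p = 8.689634060894589e-12
oracle_q = 0.4999999999956552
oracle_z = 0.4999999999956552
oracle_regime = multipartite
```

Cheats invade above `β = 0.5`; at `β = 0.8` complementation (`e = 1`)
exceeds `e* = 0.9`, so the cooperator is driven extinct and the population
ends at the multipartite state `q = z = 1/2` — confirmed independently by
replicator iteration (`oracle_p ≈ 0`).  Note `e = 1 < e** = 2.5`: this
multipartite population is *less* productive than the monopartite
ancestor it replaced.

The same from Python, plus a simulation of an 8-gene genome at MOI 5:

```python
from cheatsplit import abm

result = abm.run(abm.SimConfig(n_genes=8, moi=5.0, seed=1))
print(result.outcome.label, result.outcome.n_segments)
# multipartite 2
```

— the full-length genome is gone and the gene set persists as two
mutually complementing segments (across many seeds, three- and
four-segment endpoints are the most common at this MOI).

Other entry points: `cheatsplit phase` (regime grid over `β` × `e/d`),
`simulate` / `sweep` (single runs and replicated grids, CSV out),
`parameterise` (place species with measured particle:PFU ratios and
interference strengths on the phase plane), `compare` (per-realm
DI/multipartitism fractions and their association), `fixtures`
(synthetic example inputs).

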