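# germsoma

Digital evolution of germ–soma differentiation under mutagenic metabolic
work.

## The problem

Why do multicellular organisms maintain non-reproductive somatic cells?  One
proposed force is the mutagenic side effect of energy metabolism: reactive
oxygen species damage DNA, so an organism can protect its hereditary
information by keeping some cells metabolically quiet (germ) while others do
the damaging "dirty work" (soma).  `germsoma` is an agent-based simulator
for studying this trade-off with digital organisms, aimed at researchers in
artificial life and the evolution of multicellularity.

Each *cell* is a self-replicating program: a circular genome of Avida-style
instructions executed by a virtual CPU (three 32-bit registers, stacks,
heads, message inbox), 30 instructions per update.  Cells live inside a
*multicell* — a 5×5 toroidal grid of up to 25 cells — and earn resources by
computing Boolean logic functions on environment inputs (NOT, NAND, AND,
ORNOT, OR, ANDNOT, NOR, XOR, EQUALS).  Each function's resource pool behaves
as a chemostat (one unit flows in and 1% flows out per update; a performing
cell consumes 5% of the pool).  Every function j carries a *function mutagen
level* (FML) mⱼ — a per-site probability that the performer's genome mutates
after each performance; NOT is always clean (m_NOT = 0).

A multicell that amasses 500 resources replicates through a single-cell
bottleneck: one *propagule* is drawn uniformly from its propagule-eligible
cells, mutated at a per-site rate q, and seeded into a fresh multicell that
displaces a random competitor in a world of fixed size.  Cells can renounce
propagule eligibility by executing `block_propagation`; ineligibility is
inherited by all cellular offspring and cannot be reversed.  Germ–soma
differentiation evolves when ineligible cells take on a disproportionate
share of the mutagenic work.

A cell's *workload* is the FML-weighted count of its performances,
Σⱼ nⱼ·(mⱼ/m_base) with m_base the NAND level, and the *propagule workload
difference* is mean(workload | ineligible) − mean(workload | eligible); a
positive difference with ineligible cells present is the operational
definition of soma.  The package also includes the analytic pseudo-soma
model: with destructive-mutation probability μ and resource-rate ratio r,
expected fitness of allocating a fraction f to pseudo-soma is
(1 + f(r−1))(1 − fμ), maximised at f* = ((r−1) − μ) / (2μ(r−1)), clipped to
[0, 1].

## Worked example

A hand-built differentiating genome (cells at grid positions x < y block
propagation and loop over NAND work; the rest replicate) run alone in a
mutagen-free test environment:

```python
from germsoma import (build_differentiated_fixture, isolated_run,
                      classify_soma, propagule_workload_difference, class_shares)

res = isolated_run(build_differentiated_fixture("location"), 300,
                   seed=1, base_fml=0.0)
census = res.census
germ = census[census.eligible]
soma = census[~census.eligible]
print(f"cells: {len(census)}  germ: {len(germ)}  soma: {len(soma)}")
print(f"mean soma workload: {soma.workload.mean():.2f}")
print(f"mean germ workload: {germ.workload.mean():.2f}")
print(f"propagule workload difference: {propagule_workload_difference(census):.2f}")
print(f"soma classification: {classify_soma(census)}")
```

prints

```
cells: 25  germ: 15  soma: 10
mean soma workload: 94.80
mean germ workload: 0.00
propagule workload difference: 94.80
soma classification: True
```

The ten cells below the grid diagonal blocked their own propagation and
performed all 948 mutagenic function executions (an average workload of
94.8 NAND performances each), while the fifteen eligible germ cells stayed
pristine — a positive propagule workload difference, hence true soma.
Knocking the `get_xy` instruction out of this genome removes the positional
cue, no cell differentiates, and isolated-run acquisition drops to zero.

Evolutionary runs use the same machinery at population scale:

```python
from germsoma import TreatmentConfig, World

world = World(TreatmentConfig(world_size=400, base_fml=0.00075,
                              run_length=100_000, seed=1))
world.run()
archive = world.finalize_archive()   # censuses, genealogy, event log
```

A command-line interface mirrors the library:
`germsoma run|assay|stats|model|fixtures --help`.

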