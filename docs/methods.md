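# Methods

## Model

A world holds a fixed number of multicells (default 400).  Each multicell is
a 5×5 toroidal grid of up to 25 digital cells, with nine per-function
resource pools and a tally of resources amassed toward replication.  Each
cell is a self-replicating program: a circular genome of instructions and a
virtual CPU with three 32-bit registers (AX, BX, CX; all arithmetic wraps
modulo 2³²), two depth-10 stacks (the reduced instruction set addresses
stack 0), four heads (IP, READ, WRITE, FLOW), a two-slot input buffer, a
facing direction over the Moore 8-neighbourhood, and a bounded FIFO inbox
(capacity 16, drop-oldest).

One *update* is the unit of time.  Per update, in order:

1. **Chemostat.**  Every pool P of every multicell becomes
   P + inflow − outflow·P (defaults 1.0 and 0.01, fixed point 100).
2. **Execution.**  Every cell executes exactly 30 instructions, cells
   iterated in fixed grid order (multicell 0 cell 0 first).  Cells born
   during the current update start executing at the next one.
3. **Replication.**  Every multicell whose tally reaches 500 replicates, in
   random order: a propagule is drawn uniformly from its eligible cells,
   mutated per-site at rate q, and seeded as the single central cell of a
   fresh multicell (empty pools, zero tally) that displaces a uniformly
   chosen *other* world slot.  The parent's tally resets to zero.  If no
   cell is eligible, the replication fails: by default the tally resets and
   the multicell lives on (a config flag substitutes death).

### Instruction set

Only the coordination instructions are fixed by the study design; the rest
of the set is a documented reconstruction of a reduced Avida-style heads
set: 30 instructions — three no-op labels (`nop-a/b/c`),
conditionals (`if-less`, `if-n-equ`, `if-label`, `if_propagule_eligible`,
`if_propagule_ineligible`), head movement (`mov-head`, `jmp-head`,
`h-search`), replication (`h-alloc`, `h-copy`, `h-divide`), stack and
arithmetic (`push`, `pop`, `swap`, `inc`, `dec`, `add`, `sub`), `nand` (from
which all nine rewarded logic functions are composable), `io`, rotation
(`rotate-l/r`), and the coordination set (`get_xy`, `send_message`,
`broadcast_message`, `retrieve_message`, `block_propagation`).  Notable
conventions:

* Labels are runs of up to three no-ops following a label-reading
  instruction; `h-search` and `if-label` consume their label and use its
  complement (A→B→C→A).  `h-search` without a label points FLOW at the next
  instruction (the copy-loop idiom).
* `io` outputs BX, credits every logic function whose bitwise result on the
  two most recent inputs equals the output (asymmetric functions match in
  either input order; with one input consumed only NOT is evaluable), then
  loads the next input into BX.  Inputs come from a deterministic per-cell
  pseudo-random 32-bit stream derived from the run seed.  Crediting all
  matched functions at once is deliberate: limited pools self-dampen any
  degenerate-input exploit.
* `h-divide` succeeds only when at least one full genome length has been
  copied; the offspring (the copied sequence, capped at 2.5× the ancestor
  length) is placed at the parent's faced neighbour, replacing any occupant,
  and inherits the parent's propagation status with a fresh CPU.  Both
  parent and offspring then draw a fresh uniform facing — without this
  rebirth re-randomisation a parent with fixed facing overwrites its own
  offspring every cycle and occupancy never exceeds two cells.
* `block_propagation` is idempotent, irreversible, heritable, and becomes a
  no-op under the `block_allowed=false` control.

### Rewards and mutagenesis

A credited performance of function j acquires 5% of pool j (or a flat 5.0
under the unlimited-resource control), adds it to the multicell tally, and
then applies the function's mutagen level mⱼ: every genome site of the
performer independently switches to a uniformly drawn *different*
instruction with probability mⱼ.  Standard treatments set mⱼ equal for all
functions except NOT (always 0); ramped treatments multiply the NAND base
level by integers 1–8 (NAND→EQUALS), so EQUALS reaches 0.006 at base
0.00075.  The multipliers are configurable.

Under the redistribution control, the mutagenic consequence of a
performance by a propagule-*eligible* cell is applied instead to the
eligible cell with the smallest accrued mutagenic workload (expected-sites
ledger mⱼ·L per event; ties uniform at random); ineligible performers still
mutate themselves.  The ledger-based ordering keeps eligible cells' loads
within one event of each other, which is the point of the control.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| world_size | 400 | multicells | study condition |
| grid | 5×5 | cells | study condition |
| replication_threshold | 500 | resources | study condition |
| inflow / outflow | 1.0 / 1% | per update | chemostat, fixed point 100 |
| consumption_fraction | 5% | of pool | study condition |
| instructions_per_update | 30 | — | study condition |
| base_fml | 0.00075 | per site per performance | focal mutagen level |
| propagule_mutation_rate q | 0.0075 | per site | Avida's conventional copy rate; configurable |
| run_length | 100,000 | updates | full runs; experiments below use 20,000 |
| replicates | 30 | — | study condition; scaled arms use 10 |
| max genome length | 2.5× ancestor | sites | bloat guard |
| inbox capacity | 16 | messages | drop-oldest FIFO |

## Hand-authored genomes

The **ancestor** (50 instructions) performs NOT — composed as NAND(a, a)
via a push/swap/pop register shuffle — and self-replicates with the classic
heads copy loop, padded with 34 neutral `nop-c` sites that provide
mutational raw material without function.  All its cells stay eligible and
its workload is identically zero, so in isolation it is an immortal
multicell: acquisition when old (updates 9,000–10,000) matches acquisition
when young (0–1,000) to within the startup transient (relative rate ≈ 1.007).

The **differentiating genomes** demonstrate the two coordination mechanisms
for conditional `block_propagation`.  The *location* genome blocks cells at
grid positions x < y (via `get_xy` + `if-less`) and sets them looping over
NAND work.  The *messaging* genome adds a second, message-recruited caste:
location-soma continually `send_message` their coordinates to the one
neighbour they face, and a cell that retrieves such a payload — and sits in
the x > y half of the grid — blocks and loops over AND work; the grid
diagonal (x = y) can never be recruited, so a germ line always persists.
Knocking out `get_xy` (location) or `retrieve_message` (messaging) removes
the corresponding caste and its resource stream.

These genomes are engineered demonstrations, not evolved objects: their
differentiation pattern is deterministic by position rather than the
idiosyncratic evolved plasticity of real runs.  Validation assays
(differentiation censuses, knockout ratios) run in a mutagen-free test
environment: under FML 0.00075 a working soma accrues ≈0.13 substitutions
per update, and mutation-corrupted soma that regain replication ability
flood the grid with heritable ineligible offspring within a few hundred
updates — a real phenomenon of the model (multicell senescence), but one
that would confound the knockout measurement.  The aging assay keeps the
FML on, since that degradation is precisely its measurand.

## Assays

* **Isolated run**: one multicell in a private environment, replication
  disabled, per-update acquisition recorded (a fixed-lifetime test
  environment; aging uses 10,000-update lifetimes).
* **Knockout**: every instance of one instruction replaced by the neutral
  `nop-c`; degradation ratio = knockout/baseline acquisition, same seed.
* **Aging**: late (9,000–10,000) over early (0–1,000) acquisition.
* **Line of descent**: parent chain from any archived multicell back to a
  seeded ancestor; per-step summaries via isolated replays of founder
  genomes under a fixed assay seed.
* **Transition analysis**: the ineligible-fraction series along a lineage is
  smoothed with a centred moving average (window 100); the transition is the
  argmax of the first difference (a constant series is flagged as
  no-transition), and germ workloads are compared one window before and
  after.
* **Defector injection**: a sampled fraction of living cells (default 10%)
  has `block_propagation` knocked out and eligibility restored; their tagged
  cell lineages (tags pass through both cell division and propagules) are
  followed for 2,000 updates.

## Numerics, randomness, determinism

All run randomness derives from a single seed via independent splitmix64
streams: one per multicell (mutagenesis draws, tie-breaks, offspring
facings) and one per cell (environment inputs); world-level events
(propagule draws, displacement targets, replication order) use a PCG64
generator from the same root.  Identical config + seed reproduces an
archive bit for bit (hash-checked in tests).  The instruction interpreter is
a single numba-compiled kernel over flat arrays; the object layer
(Cell/Multicell/World) is a view over the same arrays, so unit-level
stepping and bulk simulation share one implementation.  Workload weights
degrade to 1 for non-NOT functions when the base FML is zero, so the
control treatment's "workload" is a plain count of non-NOT performances.
Empty pools yield zero gain; a cell whose genome length is zero is inert;
`pop` on an empty stack yields 0; `push` on a full stack is a no-op.

## Scaled experiment and limitations

The three-arm dirty-work experiment (`germsoma.experiments`) compares final
ineligible-cell fractions between a mutagen-free control, the standard
FML 0.00075 arm, and the redistribution control, at a desk scale of 10
replicates × 25 multicells × 20,000 updates per arm (about 4–5 minutes on
one CPU).  This scale supports the mechanical contrasts but sits far below
the study scale for *de novo* evolution: an ancestral world turns over
roughly 600 multicell generations-equivalents per run, and the evolutionary
pathway to differentiation requires acquiring a new mutagenic logic
function, splitting the workload, and only then conditional blocking —
innovations whose expected waiting time at 25 multicells vastly exceeds the
run length, and whose first step is even locally disfavoured because an
undifferentiated clone that embraces mutagenic work poisons its own
propagules.  Evolved germ–soma differentiation should therefore be expected
only at the full scale (hundreds of multicells, ≳10⁵–10⁶ updates), which is
outside desk budgets; the scaled experiment reports whatever its arms
actually produce.  Other limitations: no cell death or motility; no indel
mutations (genome lengths change only through copy-loop variation); within-
multicell cell division is copy-error-free by default; and the pseudo-soma
model is a reconstruction of the allocation trade-off (rate × propagule
integrity under uniform propagule choice) whose functional form is isolated
behind `germsoma.pseudosoma` so an alternative can be swapped in.
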