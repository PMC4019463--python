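"""Cell and multicell containers.

A multicell is a 5x5 toroidal grid holding up to 25 cells, nine per-function
resource pools, and a running tally of resources amassed toward replication.
Cells carry a propagule-eligibility flag: every cell starts eligible, the
``block_propagation`` instruction makes it ineligible, and ineligibility is
absorbing — it is inherited by all cellular offspring and has no inverse.

:class:`Cell` and :class:`Multicell` are lightweight views over the flat
kernel state (:class:`germsoma.machine.State`); mutating them mutates the
simulation directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import machine
from .instructions import INSTRUCTION_SET, Genome
from .machine import Config, State, FUNCTION_NAMES, N_FUNCTIONS

__all__ = ["Cell", "Multicell", "census_frame"]


class Cell:
    """View of a single cell slot ``(m, c)``; slot index encodes position."""

    def __init__(self, state: State, cfg: Config, m: int, c: int):
        self.state = state
        self.cfg = cfg
        self.m = int(m)
        self.c = int(c)

    # -- identity and position ------------------------------------------------
    @property
    def alive(self) -> bool:
        return bool(self.state.alive[self.m, self.c])

    @property
    def position(self) -> tuple[int, int]:
        w = int(self.state.grid[0])
        return self.c % w, self.c // w

    @property
    def id(self) -> int:
        return int(self.state.cell_id[self.m, self.c])

    @property
    def parent_id(self) -> int:
        return int(self.state.cell_parent[self.m, self.c])

    # -- heredity and state ---------------------------------------------------
    @property
    def genome(self) -> Genome:
        L = int(self.state.glen[self.m, self.c])
        return Genome(self.state.genome[self.m, self.c, :L])

    @property
    def eligible(self) -> bool:
        return bool(self.state.eligible[self.m, self.c])

    @property
    def counts(self) -> np.ndarray:
        return self.state.counts[self.m, self.c].copy()

    @property
    def facing(self) -> int:
        return int(self.state.facing[self.m, self.c])

    @facing.setter
    def facing(self, d: int):
        self.state.facing[self.m, self.c] = d % 8

    @property
    def registers(self) -> tuple[int, int, int]:
        return tuple(int(v) for v in self.state.regs[self.m, self.c])

    @property
    def inbox(self) -> list[tuple[int, int]]:
        n = int(self.state.inbox_n[self.m, self.c])
        h = int(self.state.inbox_head[self.m, self.c])
        box = self.state.inbox[self.m, self.c]
        return [
            (int(box[(h + i) % machine.INBOX_CAPACITY, 0]),
             int(box[(h + i) % machine.INBOX_CAPACITY, 1]))
            for i in range(n)
        ]

    @property
    def mutagenesis_ledger(self) -> float:
        return float(self.state.ledger[self.m, self.c])

    def step(self, update: int = 0) -> None:
        """Execute exactly one instruction (one execution slot)."""
        machine.step_cell(self.state, self.cfg, self.m, self.c, update)

    def run_update(self, update: int = 0) -> None:
        """Execute one full update: exactly 30 instruction slots."""
        machine.run_cell_update(self.state, self.cfg, self.m, self.c, update)

    def set_block(self) -> "Cell":
        """Make the cell propagule-ineligible; idempotent and irreversible."""
        self.state.eligible[self.m, self.c] = False
        return self


class Multicell:
    """View of one multicell slot: grid of cells, pools, replication tally."""

    def __init__(self, state: State, cfg: Config, m: int):
        self.state = state
        self.cfg = cfg
        self.m = int(m)

    @property
    def n_cells(self) -> int:
        return int(np.sum(self.state.alive[self.m]))

    @property
    def pools(self) -> np.ndarray:
        return self.state.pools[self.m]

    @property
    def tally(self) -> float:
        return float(self.state.tally[self.m])

    @property
    def age(self) -> int:
        return int(self.state.age[self.m])

    def cell(self, c: int) -> Cell:
        return Cell(self.state, self.cfg, self.m, c)

    def cell_at(self, x: int, y: int) -> Cell:
        w = int(self.state.grid[0])
        return self.cell((y % int(self.state.grid[1])) * w + x % w)

    def cells(self) -> list[Cell]:
        return [self.cell(c) for c in np.flatnonzero(self.state.alive[self.m])]

    def seed(self, genome: Genome | np.ndarray, x: int | None = None,
             y: int | None = None, *, eligible: bool = True, born: int = -1) -> Cell:
        """Place a fresh founder cell (defaults to the grid centre)."""
        w, h = int(self.state.grid[0]), int(self.state.grid[1])
        if x is None:
            x, y = w // 2, h // 2
        ops = genome.ops if isinstance(genome, Genome) else np.asarray(genome)
        machine.seed_cell(self.state, self.m, (y % h) * w + (x % w), ops,
                          eligible=eligible, born=born)
        return self.cell_at(x, y)

    # -- operations -----------------------------------------------------------
    def place_offspring(self, parent: Cell, offspring_genome: Genome,
                        update: int = 0) -> Cell:
        """Place an offspring at the parent's faced neighbour (replacing any
        occupant); the offspring inherits the parent's propagation status."""
        t = int(machine._neighbour(self.state, parent.c, parent.facing))
        L = len(offspring_genome)
        self.state.childbuf[self.m, parent.c, :L] = offspring_genome.ops
        machine._init_offspring(self.state, self.m, parent.c, t, L, update)
        return self.cell(t)

    def reward_function(self, cell: Cell, j: int, mode: str = "limited") -> float:
        """Resource gain for one credited performance of function ``j``.

        Limited mode consumes 5% of the pool; unlimited mode grants a fixed
        amount and leaves the pool untouched.  The tally and the cell's
        performance count advance either way.
        """
        if mode not in ("limited", "unlimited"):
            raise ValueError("mode must be 'limited' or 'unlimited'")
        if mode == "unlimited":
            gain = self.cfg.unlimited_amount
            self.state.tally[self.m] += gain
            self.state.counts[self.m, cell.c, j] += 1
            return float(gain)
        cfg = self.cfg._replace(unlimited=np.zeros(N_FUNCTIONS, dtype=np.bool_))
        return float(machine._reward_only(self.state, cfg, self.m, cell.c, j))

    def apply_fml(self, cell: Cell, j: int) -> int:
        """Mutagenise the performing cell per the FML of function ``j``:
        each site independently replaced by a different instruction with
        probability ``m_j``.  Returns the number of sites changed."""
        mj = float(self.cfg.fml[j])
        if mj <= 0.0:
            return 0
        n = int(machine._mutate_sites(self.state, self.m, cell.c, mj))
        self.state.ledger[self.m, cell.c] += mj * int(self.state.glen[self.m, cell.c])
        return n

    def apply_fml_redistributed(self, j: int) -> Cell | None:
        """Apply the mutagenic effect of one performance of ``j`` to the
        eligible cell with the smallest accrued mutagenic workload (ties
        broken uniformly at random); ``None`` when no cell is eligible."""
        mj = float(self.cfg.fml[j])
        t = int(machine._least_loaded_eligible(self.state, self.m))
        if t < 0:
            return None
        if mj > 0.0:
            machine._mutate_sites(self.state, self.m, t, mj)
            self.state.ledger[self.m, t] += mj * int(self.state.glen[self.m, t])
        return self.cell(t)

    def select_propagule(self, rng: np.random.Generator) -> Cell | None:
        """Uniform draw over propagule-eligible cells; ``None`` if there are
        none (a valid outcome — the multicell cannot replicate)."""
        elig = np.flatnonzero(self.state.alive[self.m] & self.state.eligible[self.m])
        if len(elig) == 0:
            return None
        return self.cell(int(rng.choice(elig)))

    def deliver_message(self, sender: Cell, payload: tuple[int, int],
                        broadcast: bool = False) -> int:
        """Deliver ``payload`` to the faced neighbour (targeted) or to all
        occupied Moore neighbours (broadcast); returns recipients reached."""
        v0 = np.uint64(int(payload[0]) & 0xFFFFFFFF)
        v1 = np.uint64(int(payload[1]) & 0xFFFFFFFF)
        dirs = range(8) if broadcast else [sender.facing]
        n = 0
        for d in dirs:
            t = int(machine._neighbour(self.state, sender.c, d))
            if self.state.alive[self.m, t]:
                machine._inbox_push(self.state, self.m, t, v0, v1)
                n += 1
        return n

    def census(self, base_fml: float | None = None) -> pd.DataFrame:
        return census_frame(self.state, self.cfg, [self.m], base_fml=base_fml)


def census_frame(state: State, cfg: Config, multicells=None,
                 mc_ids: np.ndarray | None = None,
                 base_fml: float | None = None) -> pd.DataFrame:
    """Census snapshot: one row per living cell.

    Columns: multicell id, cell id, x, y, eligible, n_<function> for the nine
    logic functions, workload (FML-weighted performance count).
    """
    from .stats import workload_weights

    if multicells is None:
        multicells = range(state.alive.shape[0])
    fml = np.asarray(cfg.fml, dtype=float)
    if base_fml is None:
        base_fml = float(fml[1])  # NAND
    w = workload_weights(fml, base_fml)
    width = int(state.grid[0])
    rows = []
    for m in multicells:
        mc_id = int(mc_ids[m]) if mc_ids is not None else int(m)
        for c in np.flatnonzero(state.alive[m]):
            counts = state.counts[m, c]
            rows.append(
                (mc_id, int(state.cell_id[m, c]), int(c % width), int(c // width),
                 bool(state.eligible[m, c]), *[int(v) for v in counts],
                 float(counts @ w))
            )
    cols = (["multicell_id", "cell_id", "x", "y", "eligible"]
            + [f"n_{f}" for f in FUNCTION_NAMES] + ["workload"])
    return pd.DataFrame(rows, columns=cols)
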