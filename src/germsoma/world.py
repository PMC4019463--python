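"""The world: a fixed-size population of competing multicells.

Each update: (1) chemostat flows apply to every resource pool of every
multicell (one unit in, 1% out); (2) every cell executes 30 instructions, in
fixed grid order; (3) every multicell whose tally has reached the replication
threshold (500 resources) replicates, in random order — a propagule is drawn
uniformly from its propagule-eligible cells, mutated at the per-site rate
``q``, and seeded as the single founder cell of a fresh multicell that
displaces a uniformly chosen *other* multicell.  The population size is
constant after initialisation; the single-cell bottleneck plus displacement
is the only between-multicell selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import machine
from .instructions import INSTRUCTION_SET, Genome
from .io import RunArchive
from .machine import FUNCTION_NAMES, N_FUNCTIONS
from .multicell import Multicell, census_frame

__all__ = [
    "TreatmentConfig",
    "World",
    "chemostat_step",
    "mutate_propagule",
    "run",
]

_NOT = FUNCTION_NAMES.index("NOT")
_NAND = FUNCTION_NAMES.index("NAND")

#: ramped-treatment integer multipliers of the base (NAND) FML, NAND..EQUALS;
#: EQUALS at 8x the base 0.00075 gives 0.006, the most damaging function.
DEFAULT_RAMP_MULTIPLIERS = (1, 2, 3, 4, 5, 6, 7, 8)


@dataclass
class TreatmentConfig:
    """Treatment parameters and world constants for one experiment arm."""

    world_size: int = 400
    grid: tuple[int, int] = (5, 5)
    replication_threshold: float = 500.0
    consumption_fraction: float = 0.05
    inflow: float = 1.0
    outflow_fraction: float = 0.01
    instructions_per_update: int = 30
    base_fml: float = 0.00075
    mode: str = "standard"              # "standard" | "ramped"
    ramp_multipliers: tuple = DEFAULT_RAMP_MULTIPLIERS
    redistribute: bool = False
    block_allowed: bool = True
    unlimited_functions: tuple = ()     # function names rewarded at a flat rate
    unlimited_amount: float = 5.0
    propagule_mutation_rate: float = 0.0075
    run_length: int = 100_000
    replicates: int = 30
    seed: int = 0
    max_genome_factor: float = 2.5
    on_failed_replication: str = "reset"  # "reset" | "die"
    snapshot_interval: int = 0          # 0 = final census only

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.world_size < 1:
            raise ValueError("world_size must be >= 1")
        if len(self.grid) != 2 or min(self.grid) < 2:
            raise ValueError("grid must be a (width, height) pair, each >= 2")
        if self.mode not in ("standard", "ramped"):
            raise ValueError("mode must be 'standard' or 'ramped'")
        if self.mode == "ramped" and len(self.ramp_multipliers) != 8:
            raise ValueError("ramped mode needs 8 multipliers (NAND..EQUALS)")
        if not 0.0 <= self.propagule_mutation_rate <= 1.0:
            raise ValueError("propagule_mutation_rate must lie in [0, 1]")
        if self.base_fml < 0:
            raise ValueError("base_fml must be non-negative")
        if self.on_failed_replication not in ("reset", "die"):
            raise ValueError("on_failed_replication must be 'reset' or 'die'")
        if self.run_length < 0 or self.replicates < 1:
            raise ValueError("run_length >= 0 and replicates >= 1 required")
        unknown = set(self.unlimited_functions) - set(FUNCTION_NAMES)
        if unknown:
            raise ValueError(f"unknown functions {sorted(unknown)}")

    @property
    def fml_table(self) -> np.ndarray:
        """Per-function mutagen levels; NOT is always non-mutagenic."""
        fml = np.zeros(N_FUNCTIONS)
        if self.mode == "standard":
            fml[1:] = self.base_fml
        else:
            fml[1:] = self.base_fml * np.asarray(self.ramp_multipliers, dtype=float)
        fml[_NOT] = 0.0
        return fml

    def kernel_config(self, gmax: int) -> machine.Config:
        unlimited = np.array([f in self.unlimited_functions for f in FUNCTION_NAMES])
        return machine.make_config(
            self.fml_table,
            consumption=self.consumption_fraction,
            unlimited=unlimited,
            unlimited_amount=self.unlimited_amount,
            redistribute=self.redistribute,
            block_allowed=self.block_allowed,
            ipu=self.instructions_per_update,
            gmax=gmax,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["ramp_multipliers"] = list(self.ramp_multipliers)
        d["unlimited_functions"] = list(self.unlimited_functions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentConfig":
        d = dict(d)
        for key in ("grid", "ramp_multipliers", "unlimited_functions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "TreatmentConfig":
        import tomllib

        return cls.from_dict(tomllib.loads(Path(path).read_text()))

    def to_toml(self, path) -> None:
        from .io import _toml_dump

        Path(path).write_text(_toml_dump(self.to_dict()))


def chemostat_step(pool: float, inflow: float = 1.0,
                   outflow_fraction: float = 0.01) -> float:
    """One chemostat tick: one unit flows in, 1% of the pool flows out.

    Fixed point at ``inflow / outflow_fraction`` (100 with the defaults).
    """
    return pool + inflow - outflow_fraction * pool


def mutate_propagule(genome: Genome | np.ndarray, q: float,
                     rng: np.random.Generator) -> Genome:
    """Per-site substitution at probability ``q``; each hit site is replaced
    by a uniformly drawn *different* instruction.  Length is preserved."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    ops = (genome.ops if isinstance(genome, Genome) else np.asarray(genome)).copy()
    hits = np.flatnonzero(rng.random(len(ops)) < q)
    for i in hits:
        r = rng.integers(len(INSTRUCTION_SET) - 1)
        if r >= ops[i]:
            r += 1
        ops[i] = r
    return Genome(ops)


class World:
    """A population of ``world_size`` multicells, all seeded at start."""

    def __init__(self, config: TreatmentConfig, ancestor: Genome | None = None,
                 seed: int | None = None, replication_enabled: bool = True):
        config.validate()
        if ancestor is None:
            from .fixtures import build_ancestor

            ancestor = build_ancestor()
        self.config = config
        self.ancestor = ancestor
        self.seed = int(config.seed if seed is None else seed)
        self.replication_enabled = replication_enabled
        gmax = max(len(ancestor), int(config.max_genome_factor * len(ancestor)))
        self.cfg = config.kernel_config(gmax)
        ss = np.random.SeedSequence(self.seed)
        kernel_ss, py_ss = ss.spawn(2)
        self.rng = np.random.Generator(np.random.PCG64(py_ss))
        w, h = config.grid
        self.state = machine.make_state(config.world_size, gmax, kernel_ss,
                                        width=w, height=h)
        self.update_count = 0
        self.mc_ids = np.arange(config.world_size, dtype=np.int64)
        self._next_mc_id = config.world_size
        self.archive = RunArchive(config_dict=config.to_dict(), seed=self.seed)
        cx, cy = w // 2, h // 2
        for m in range(config.world_size):
            Multicell(self.state, self.cfg, m).seed(ancestor, cx, cy, born=-1)
            self.archive.record_seed_multicell(m, ancestor.ops)

    # -- views ----------------------------------------------------------------
    @property
    def n_multicells(self) -> int:
        return self.state.alive.shape[0]

    def multicell(self, m: int) -> Multicell:
        return Multicell(self.state, self.cfg, m)

    def census(self) -> pd.DataFrame:
        return census_frame(self.state, self.cfg, mc_ids=self.mc_ids,
                            base_fml=self.config.base_fml)

    def ineligible_fraction(self) -> float:
        alive = self.state.alive
        n = int(alive.sum())
        if n == 0:
            return float("nan")
        return float((alive & ~self.state.eligible).sum() / n)

    def tag_frequency(self) -> float:
        alive = self.state.alive
        n = int(alive.sum())
        return float((alive & self.state.tag).sum() / n) if n else float("nan")

    # -- dynamics -------------------------------------------------------------
    def update(self) -> None:
        """One world update: chemostat, execution, then replications."""
        S = self.state
        S.pools[:, :] += self.config.inflow - self.config.outflow_fraction * S.pools
        machine.run_update(S, self.cfg, self.update_count)
        for m, c, cid in machine.drain_blocklog(S):
            self.archive.log(self.update_count, "block", mc=int(self.mc_ids[m]),
                             cell=cid, slot=f"{m}:{c}")
        if self.replication_enabled:
            ready = np.flatnonzero(S.tally >= self.config.replication_threshold)
            if len(ready):
                self.rng.shuffle(ready)
                for m in ready:
                    if S.tally[m] >= self.config.replication_threshold:
                        self.replicate_multicell(int(m))
        self.update_count += 1
        interval = self.config.snapshot_interval
        if interval and self.update_count % interval == 0:
            self.archive.add_census(self.update_count, self.census())

    def replicate_multicell(self, m: int) -> int | None:
        """Replicate multicell ``m`` through its single-cell bottleneck.

        Returns the world slot of the offspring, or None when no cell is
        propagule-eligible (a failed replication; the parent's tally resets,
        or the multicell dies, per configuration).
        """
        S = self.state
        mc = self.multicell(m)
        prop = mc.select_propagule(self.rng)
        if prop is None:
            self.archive.log(self.update_count, "failed_replication",
                             parent=int(self.mc_ids[m]))
            if self.config.on_failed_replication == "die":
                machine.clear_multicell(S, m)
            else:
                S.tally[m] = 0.0
            return None
        founder = mutate_propagule(prop.genome, self.config.propagule_mutation_rate,
                                   self.rng)
        # displacement target: uniform over all slots except the parent's
        v = int(self.rng.integers(self.n_multicells - 1))
        if v >= m:
            v += 1
        tag = bool(S.tag[m, prop.c])
        machine.clear_multicell(S, v)
        w, h = self.config.grid
        machine.seed_cell(S, v, (h // 2) * w + w // 2, founder.ops,
                          eligible=True, born=self.update_count, tag=tag,
                          parent_id=prop.id)
        new_id = self._next_mc_id
        self._next_mc_id += 1
        self.archive.record_replication(new_id, int(self.mc_ids[m]),
                                        self.update_count, founder.ops,
                                        propagule_cell_id=prop.id)
        self.mc_ids[v] = new_id
        S.tally[m] = 0.0
        return v

    def run(self, n_updates: int | None = None) -> "World":
        n = self.config.run_length if n_updates is None else int(n_updates)
        for _ in range(n):
            self.update()
        return self

    def finalize_archive(self) -> RunArchive:
        have = [u for u, _ in self.archive.censuses]
        if self.update_count not in have:
            self.archive.add_census(self.update_count, self.census())
        return self.archive


def run(config: TreatmentConfig, ancestor: Genome | None = None,
        seed: int | None = None, outdir=None) -> RunArchive:
    """Execute one full run and return (optionally save) its archive."""
    world = World(config, ancestor=ancestor, seed=seed)
    world.run()
    archive = world.finalize_archive()
    if outdir is not None:
        archive.save(outdir)
    return archive
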