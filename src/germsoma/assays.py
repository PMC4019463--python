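"""Experimental procedures on evolved genomes and populations.

* :func:`isolated_run` — seed one multicell in a private test environment
  (its own chemostat pools, multicell replication disabled) and record its
  per-update resource acquisition over a fixed lifetime.
* :func:`knockout` / :func:`knockout_assay` — replace every instance of a
  coordination instruction with the neutral no-op and compare acquisition
  against the unmodified genome under the same seed.
* :func:`aging_assay` — relative resource-acquisition rate of an old
  multicell (updates 9,000-10,000) versus a young one (0-1,000).
* :func:`line_of_descent` / :func:`transition_analysis` — reconstruct the
  ancestor-to-focal multicell genealogy and locate the point where the
  fraction of propagule-ineligible cells rises sharply.
* :func:`defector_injection` — convert a fraction of living cells into
  always-eligible defectors and follow their lineage frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .instructions import INSTRUCTION_SET, Genome
from .io import RunArchive
from .machine import FUNCTION_NAMES
from .stats import workload_weights
from .world import TreatmentConfig, World

__all__ = [
    "AssayResult",
    "isolated_run",
    "knockout",
    "knockout_assay",
    "aging_assay",
    "LineageRecord",
    "line_of_descent",
    "detect_transition",
    "transition_analysis",
    "defector_injection",
]

_BLOCK = "block_propagation"


@dataclass
class AssayResult:
    """Resource-acquisition time series of one isolated multicell."""

    gains: np.ndarray                 # per-update resource acquisition
    world: World = None
    censuses: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.gains.sum())

    def acquired(self, start: int, stop: int) -> float:
        """Resources acquired in the update window [start, stop)."""
        return float(self.gains[start:stop].sum())

    @property
    def census(self) -> pd.DataFrame:
        return self.world.census()


def _default_config(n_updates: int, base_fml: float, seed: int) -> TreatmentConfig:
    return TreatmentConfig(world_size=1, base_fml=base_fml,
                           run_length=n_updates, seed=seed)


def isolated_run(founder: Genome, n_updates: int, *, base_fml: float = 0.00075,
                 config: TreatmentConfig | None = None, seed: int = 0,
                 snapshot_every: int = 0) -> AssayResult:
    """Run one multicell alone for ``n_updates`` and record its acquisition.

    The test environment disables multicell replication, so the tally
    accumulates without bound and acquisition speed is measurable over the
    whole lifetime.  Same founder and seed give an identical series.
    """
    if n_updates < 1:
        raise ValueError("n_updates must be >= 1")
    if config is None:
        config = _default_config(n_updates, base_fml, seed)
    else:
        config = dc_replace(config, world_size=1, run_length=n_updates, seed=seed)
    world = World(config, ancestor=founder, replication_enabled=False)
    gains = np.zeros(n_updates)
    censuses = []
    prev = 0.0
    for t in range(n_updates):
        world.update()
        cur = float(world.state.tally[0])
        gains[t] = cur - prev
        prev = cur
        if snapshot_every and (t + 1) % snapshot_every == 0:
            censuses.append((t + 1, world.census()))
    return AssayResult(gains=gains, world=world, censuses=censuses)


def knockout(genome: Genome, instruction_name: str) -> Genome:
    """Replace every instance of ``instruction_name`` with the neutral no-op.

    Length and all other sites are untouched; idempotent, and knockouts of
    distinct instructions commute.
    """
    if instruction_name not in INSTRUCTION_SET:
        raise KeyError(f"unknown instruction {instruction_name!r}")
    return genome.replaced(instruction_name, "nop-c")


def knockout_assay(founder: Genome, instruction_name: str,
                   n_updates: int = 1000, *, base_fml: float = 0.00075,
                   seed: int = 0) -> dict:
    """Degradation ratio of a knocked-out founder versus the unmodified one.

    Both variants run under the same seed.  ``ratio`` < 1 means the knocked-
    out instruction was required for full performance; NaN (flagged) when the
    unmodified founder acquires nothing.
    """
    baseline = isolated_run(founder, n_updates, base_fml=base_fml, seed=seed)
    modified = isolated_run(knockout(founder, instruction_name), n_updates,
                            base_fml=base_fml, seed=seed)
    b, k = baseline.total, modified.total
    return {
        "instruction": instruction_name,
        "baseline": b,
        "knockout": k,
        "ratio": (k / b) if b > 0 else float("nan"),
    }


def aging_assay(founder: Genome, *, base_fml: float = 0.00075, seed: int = 0,
                n_updates: int = 10_000, young: tuple = (0, 1000),
                old: tuple = (9000, 10_000)) -> dict:
    """Relative resource-acquisition rate of an old versus a young multicell.

    A relative rate of one means the old multicell consumes as much as it did
    in its youth (the immortal baseline); performing mutagenic work drives it
    below one.  NaN (flagged) when nothing is acquired while young.
    """
    res = isolated_run(founder, n_updates, base_fml=base_fml, seed=seed)
    early = res.acquired(*young)
    late = res.acquired(*old)
    return {
        "early_rate": early,
        "late_rate": late,
        "relative_rate": (late / early) if early > 0 else float("nan"),
        "result": res,
    }


# ---------------------------------------------------------------------------
# line of descent

@dataclass
class LineageRecord:
    """Ancestor-to-focal chain of multicell founders along a genealogy."""

    ids: list[int]                    # ordered, ancestor first
    archive: RunArchive
    summaries: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def founder(self, step: int) -> Genome:
        return self.archive.founder_genome(self.ids[step])

    def compute_summaries(self, replay_updates: int = 1000, *,
                          base_fml: float | None = None, seed: int = 0) -> pd.DataFrame:
        """Per-step census summaries via isolated replays of the founders
        (fixed assay seed): ineligible fraction and class mean workloads."""
        if base_fml is None:
            base_fml = float(self.archive.config_dict.get("base_fml", 0.00075))
        rows = []
        for mc_id in self.ids:
            res = isolated_run(self.archive.founder_genome(mc_id),
                               replay_updates, base_fml=base_fml, seed=seed)
            census = res.census
            elig = census["eligible"].astype(bool)
            wl = census["workload"]
            rows.append({
                "multicell_id": mc_id,
                "ineligible_fraction": float((~elig).mean()) if len(census) else 0.0,
                "mean_eligible_workload": float(wl[elig].mean()) if elig.any() else float("nan"),
                "mean_ineligible_workload": float(wl[~elig].mean()) if (~elig).any() else float("nan"),
            })
        self.summaries = pd.DataFrame(rows)
        return self.summaries


def line_of_descent(archive: RunArchive, focal_multicell_id: int) -> LineageRecord:
    """Follow the parent chain from a focal multicell back to a seeded
    ancestor (parent id -1).  A broken chain raises, naming the missing id."""
    ids = []
    cur = int(focal_multicell_id)
    while True:
        if cur not in archive.records:
            raise KeyError(f"genealogy chain broken: multicell id {cur} not archived")
        ids.append(cur)
        parent = archive.records[cur].parent_id
        if parent < 0:
            break
        cur = parent
    ids.reverse()
    return LineageRecord(ids=ids, archive=archive)


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    return (pd.Series(series)
            .rolling(window, center=True, min_periods=1).mean().to_numpy())


def detect_transition(ineligible_series, window: int = 100) -> int | None:
    """Index of the sharpest rise of the smoothed ineligible-cell fraction.

    The series is smoothed with a centred moving average of length
    ``window``; the transition is the position of the maximum first
    difference.  Returns None (no transition) when the smoothed series never
    rises.
    """
    series = np.asarray(ineligible_series, dtype=float)
    if len(series) < 2:
        return None
    diffs = np.diff(_smooth(series, window))
    if np.nanmax(diffs) <= 1e-12:
        return None
    return int(np.nanargmax(diffs)) + 1


def transition_analysis(lineage, window: int = 100):
    """Locate the germ-soma transition along a lineage and compare the mean
    propagule-eligible (germ) workload ``window`` steps before and after it.

    ``lineage`` is a LineageRecord with computed summaries, or a DataFrame
    with columns ``ineligible_fraction`` and ``mean_eligible_workload``.
    Returns ``(transition_index, pre_mean, post_mean)``; the index is None
    when no rise exists.
    """
    if isinstance(lineage, LineageRecord):
        if lineage.summaries is None:
            lineage.compute_summaries()
        frame = lineage.summaries
    else:
        frame = lineage
    n = len(frame)
    if n <= 2 * window:
        raise ValueError(f"lineage length {n} too short for window {window}")
    idx = detect_transition(frame["ineligible_fraction"].to_numpy(), window)
    if idx is None:
        return None, float("nan"), float("nan")
    germ = _smooth(frame["mean_eligible_workload"].to_numpy(dtype=float), window)
    pre = float(germ[max(idx - window, 0)])
    post = float(germ[min(idx + window, n - 1)])
    return idx, pre, post


# ---------------------------------------------------------------------------
# defectors

def defector_injection(world: World, fraction: float,
                       follow_updates: int = 2000,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Convert a fraction of all living cells into defectors and follow them.

    Each sampled cell has ``block_propagation`` knocked out of its genome and
    is marked propagule-eligible; its cell lineage is tagged (tags pass to
    cellular offspring and through propagules).  Returns the per-update
    frequency of defector-descended cells, starting at injection.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    S = world.state
    living = np.argwhere(S.alive)
    if len(living) == 0:
        raise ValueError("world contains no living cells")
    if rng is None:
        rng = world.rng
    k = max(1, int(round(fraction * len(living))))
    chosen = living[rng.choice(len(living), size=k, replace=False)]
    S.tag[:, :] = False
    block_op = INSTRUCTION_SET.opcode(_BLOCK)
    neutral = INSTRUCTION_SET.neutral_opcode
    for m, c in chosen:
        L = int(S.glen[m, c])
        g = S.genome[m, c, :L]
        g[g == block_op] = neutral
        S.eligible[m, c] = True
        S.tag[m, c] = True
        world.archive.log(world.update_count, "defector_tag",
                          mc=int(world.mc_ids[m]), cell=int(S.cell_id[m, c]))
    freqs = np.zeros(follow_updates + 1)
    freqs[0] = world.tag_frequency()
    for t in range(follow_updates):
        world.update()
        freqs[t + 1] = world.tag_frequency()
    return freqs
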