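"""Plain-text formats and the run archive.

Genome files hold one instruction name per line; ``#`` starts a comment.
Round-tripping a genome through write/read is byte-stable.  A run archive is
a self-describing directory: config snapshot, census CSV series, genealogy
CSV, line-oriented event log, and founder genomes — re-running from its
config and seed reproduces it bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instructions import INSTRUCTION_SET, Genome, InstructionSet

__all__ = ["read_genome", "write_genome", "GenomeFileError", "RunArchive"]


class GenomeFileError(ValueError):
    pass


def read_genome(path, iset: InstructionSet = INSTRUCTION_SET) -> Genome:
    """Read a genome text file; unknown names are rejected with line numbers."""
    path = Path(path)
    ops = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line not in iset:
            raise GenomeFileError(
                f"{path}:{lineno}: unknown instruction {line!r}")
        ops.append(line)
    if not ops:
        raise GenomeFileError(f"{path}: no instructions found")
    return Genome(ops, iset)


def write_genome(genome: Genome, path) -> None:
    Path(path).write_text("\n".join(genome.names) + "\n")


def _toml_dump(d: dict) -> str:
    lines = []
    for k, v in d.items():
        if isinstance(v, bool):
            s = "true" if v else "false"
        elif isinstance(v, (int, float)):
            s = repr(v)
        elif isinstance(v, str):
            s = json.dumps(v)
        elif isinstance(v, (list, tuple)):
            s = "[" + ", ".join(json.dumps(x) if isinstance(x, str) else repr(x)
                                for x in v) + "]"
        else:
            raise TypeError(f"cannot serialise {k}={v!r}")
        lines.append(f"{k} = {s}")
    return "\n".join(lines) + "\n"


@dataclass
class ReplicationRecord:
    offspring_id: int
    parent_id: int
    update: int
    founder: np.ndarray  # opcode array of the founder genome
    propagule_cell_id: int = -1


@dataclass
class RunArchive:
    """In-memory record of a run: genealogy, censuses, events, config."""

    config_dict: dict = field(default_factory=dict)
    seed: int = 0
    records: dict[int, ReplicationRecord] = field(default_factory=dict)
    events: list[str] = field(default_factory=list)
    censuses: list[tuple[int, pd.DataFrame]] = field(default_factory=list)

    # -- recording ------------------------------------------------------------
    def record_seed_multicell(self, mc_id: int, founder: np.ndarray) -> None:
        self.records[mc_id] = ReplicationRecord(mc_id, -1, 0, np.asarray(founder, dtype=np.int8))

    def record_replication(self, offspring_id: int, parent_id: int, update: int,
                           founder: np.ndarray, propagule_cell_id: int = -1) -> None:
        self.records[offspring_id] = ReplicationRecord(
            offspring_id, parent_id, update,
            np.asarray(founder, dtype=np.int8), propagule_cell_id)
        self.log(update, "replication",
                 offspring=offspring_id, parent=parent_id)

    def log(self, update: int, event: str, **kv) -> None:
        extras = " ".join(f"{k}={v}" for k, v in kv.items())
        self.events.append(f"update={update} event={event} {extras}".rstrip())

    def add_census(self, update: int, frame: pd.DataFrame) -> None:
        self.censuses.append((int(update), frame))

    # -- queries --------------------------------------------------------------
    def parent_of(self, mc_id: int) -> int:
        return self.records[mc_id].parent_id

    def founder_genome(self, mc_id: int) -> Genome:
        return Genome(self.records[mc_id].founder)

    @property
    def n_replications(self) -> int:
        return sum(1 for r in self.records.values() if r.parent_id >= 0)

    def genealogy_frame(self) -> pd.DataFrame:
        rows = [
            (r.offspring_id, r.parent_id, r.update,
             f"founders/mc{r.offspring_id}.genome")
            for r in sorted(self.records.values(), key=lambda r: r.offspring_id)
        ]
        return pd.DataFrame(rows, columns=["offspring_id", "parent_id", "update",
                                           "founder_genome_file"])

    def digest(self) -> str:
        """SHA-256 over a canonical serialisation (determinism checks)."""
        h = hashlib.sha256()
        h.update(json.dumps(self.config_dict, sort_keys=True, default=str).encode())
        h.update(str(self.seed).encode())
        for r in sorted(self.records.values(), key=lambda r: r.offspring_id):
            h.update(f"{r.offspring_id},{r.parent_id},{r.update},".encode())
            h.update(r.founder.tobytes())
        for line in self.events:
            h.update(line.encode())
        for upd, frame in self.censuses:
            h.update(str(upd).encode())
            h.update(frame.to_csv(index=False).encode())
        return h.hexdigest()

    # -- persistence ----------------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.toml").write_text(_toml_dump(
            {**self.config_dict, "seed": self.seed}))
        self.genealogy_frame().to_csv(outdir / "genealogy.csv", index=False)
        (outdir / "events.log").write_text("\n".join(self.events) + "\n"
                                           if self.events else "")
        founders = outdir / "founders"
        founders.mkdir(exist_ok=True)
        for r in self.records.values():
            write_genome(Genome(r.founder), founders / f"mc{r.offspring_id}.genome")
        for upd, frame in self.censuses:
            frame.to_csv(outdir / f"census_{upd:08d}.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "RunArchive":
        import tomllib

        outdir = Path(outdir)
        cfg = tomllib.loads((outdir / "config.toml").read_text())
        arch = cls(config_dict={k: v for k, v in cfg.items() if k != "seed"},
                   seed=int(cfg.get("seed", 0)))
        gen = pd.read_csv(outdir / "genealogy.csv")
        for _, row in gen.iterrows():
            g = read_genome(outdir / row["founder_genome_file"])
            arch.records[int(row["offspring_id"])] = ReplicationRecord(
                int(row["offspring_id"]), int(row["parent_id"]),
                int(row["update"]), g.ops)
        events_path = outdir / "events.log"
        if events_path.exists():
            arch.events = [l for l in events_path.read_text().splitlines() if l]
        for f in sorted(outdir.glob("census_*.csv")):
            arch.censuses.append((int(f.stem.split("_")[1]), pd.read_csv(f)))
        return arch
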