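"""Multi-replicate treatment experiments.

The dirty-work experiment compares the evolved abundance of
propagule-ineligible cells across three arms: a mutagen-free control
(FML 0.0), the standard mutagenic treatment (all non-NOT functions at the
base FML), and the redistribution control (same FML, but mutagenic
consequences of eligible cells' work are shifted onto the least-worked
eligible cell, removing the benefit of concentrating dirty work).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import rank_sum_test
from .world import TreatmentConfig, World

__all__ = ["DirtyWorkResult", "run_arm", "dirty_work_experiment"]


@dataclass
class DirtyWorkResult:
    """Per-replicate final ineligible-cell fractions for the three arms."""

    control: np.ndarray
    standard: np.ndarray
    redistributed: np.ndarray
    p_standard_vs_control: float   # one-sided (standard > control)
    u_statistic: float

    @property
    def means(self) -> dict:
        return {
            "control": float(self.control.mean()),
            "standard": float(self.standard.mean()),
            "redistributed": float(self.redistributed.mean()),
        }


def run_arm(base_fml: float, *, redistribute: bool = False,
            world_size: int = 25, run_length: int = 20_000,
            replicates: int = 10, seed: int = 0,
            block_allowed: bool = True) -> np.ndarray:
    """Final ineligible-cell fraction for each replicate of one arm."""
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2 ** 31)
    out = np.zeros(replicates)
    for i, s in enumerate(seeds):
        config = TreatmentConfig(world_size=world_size, base_fml=base_fml,
                                 run_length=run_length, replicates=replicates,
                                 redistribute=redistribute,
                                 block_allowed=block_allowed, seed=int(s))
        world = World(config)
        world.run(run_length)
        frac = world.ineligible_fraction()
        out[i] = 0.0 if np.isnan(frac) else frac
    return out


def dirty_work_experiment(*, base_fml: float = 0.00075, world_size: int = 25,
                          run_length: int = 20_000, replicates: int = 10,
                          seed: int = 0) -> DirtyWorkResult:
    """Three-arm comparison of evolved propagule-ineligible fractions.

    Arms run ``replicates`` independent worlds each (seeds derived from
    ``seed``); the headline test is the one-sided rank-sum comparison of the
    mutagenic arm against the FML-0 control.
    """
    control = run_arm(0.0, world_size=world_size, run_length=run_length,
                      replicates=replicates, seed=seed)
    standard = run_arm(base_fml, world_size=world_size, run_length=run_length,
                       replicates=replicates, seed=seed + 1)
    redistributed = run_arm(base_fml, redistribute=True, world_size=world_size,
                            run_length=run_length, replicates=replicates,
                            seed=seed + 2)
    u, p = rank_sum_test(standard, control, alternative="greater")
    return DirtyWorkResult(control=control, standard=standard,
                           redistributed=redistributed,
                           p_standard_vs_control=p, u_statistic=u)
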