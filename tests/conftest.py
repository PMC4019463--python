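import numpy as np
import pytest

from germsoma import machine
from germsoma.instructions import Genome
from germsoma.multicell import Cell, Multicell


@pytest.fixture(scope="session")
def ancestor():
    from germsoma.fixtures import build_ancestor

    return build_ancestor()


def make_multicell(fml=None, *, seed=7, n_multicells=1, gmax=128, grid=(5, 5),
                   **cfg_kw):
    """A bare simulation state with one (or more) empty multicells."""
    if fml is None:
        fml = np.zeros(machine.N_FUNCTIONS)
    state = machine.make_state(n_multicells, gmax, np.random.SeedSequence(seed),
                               width=grid[0], height=grid[1])
    cfg = machine.make_config(fml, **cfg_kw)
    return state, cfg


def cell_with(genome, *, fml=None, x=2, y=2, seed=7, **cfg_kw):
    """One fresh cell holding ``genome`` on an otherwise empty grid."""
    state, cfg = make_multicell(fml, seed=seed, **cfg_kw)
    ops = genome.ops if isinstance(genome, Genome) else Genome(genome).ops
    machine.seed_cell(state, 0, y * 5 + x, ops)
    mc = Multicell(state, cfg, 0)
    return mc, mc.cell(y * 5 + x)
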