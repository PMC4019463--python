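"""Multicell container: placement, rewards, mutagenesis, eligibility, messages."""

import numpy as np
import pytest

from germsoma import machine
from germsoma.instructions import Genome
from germsoma.multicell import Multicell
from conftest import cell_with, make_multicell


def _grid_cell(mc, x, y, genome=("nop-a",), eligible=True):
    machine.seed_cell(mc.state, mc.m, y * 5 + x, Genome(list(genome)).ops,
                      eligible=eligible)
    return mc.cell_at(x, y)


class TestPlacement:
    def test_offspring_at_faced_neighbour(self):
        mc, parent = cell_with(["nop-a"], x=0, y=0)
        parent.facing = 0  # east
        child = mc.place_offspring(parent, Genome(["nop-b"]))
        assert child.position == (1, 0)
        assert child.genome == Genome(["nop-b"])

    def test_torus_wrap(self):
        mc, parent = cell_with(["nop-a"], x=4, y=4)
        parent.facing = 0  # east -> wraps to x=0
        child = mc.place_offspring(parent, Genome(["nop-b"]))
        assert child.position == (0, 4)

    def test_occupant_replaced(self):
        mc, parent = cell_with(["nop-a"], x=0, y=0)
        parent.facing = 0
        resident = _grid_cell(mc, 1, 0)
        old_id = resident.id
        child = mc.place_offspring(parent, Genome(["nop-c"]))
        assert mc.n_cells == 2
        assert child.id != old_id

    def test_eligibility_inherited(self):
        mc, parent = cell_with(["nop-a"], x=0, y=0)
        parent.set_block()
        child = mc.place_offspring(parent, Genome(["nop-a"]))
        assert not child.eligible


class TestReward:
    def test_limited_gain_is_5_percent(self):
        mc, cell = cell_with(["nop-a"])
        mc.pools[1] = 100.0
        gain = mc.reward_function(cell, 1)
        assert gain == pytest.approx(5.0)
        assert mc.pools[1] == pytest.approx(95.0)
        assert mc.tally == pytest.approx(5.0)
        assert cell.counts[1] == 1

    def test_empty_pool_gains_nothing(self):
        mc, cell = cell_with(["nop-a"])
        assert mc.reward_function(cell, 2) == 0.0

    def test_diminishing_returns(self):
        mc, cell = cell_with(["nop-a"])
        mc.pools[1] = 100.0
        gains = [mc.reward_function(cell, 1) for _ in range(2)]
        assert gains == [pytest.approx(5.0), pytest.approx(4.75)]

    def test_unlimited_mode_fixed_reward(self):
        mc, cell = cell_with(["nop-a"])
        mc.pools[0] = 100.0
        g1 = mc.reward_function(cell, 0, mode="unlimited")
        g2 = mc.reward_function(cell, 0, mode="unlimited")
        assert g1 == g2 == pytest.approx(5.0)
        assert mc.pools[0] == pytest.approx(100.0)  # pool untouched

    def test_pool_decrement_equals_tally_increment(self):
        mc, cell = cell_with(["nop-a"])
        mc.pools[:] = 73.0
        before = mc.pools.sum()
        for j in range(9):
            mc.reward_function(cell, j)
        assert before - mc.pools.sum() == pytest.approx(mc.tally)


class TestFml:
    def test_zero_fml_never_mutates(self):
        mc, cell = cell_with(["io"] * 50)
        assert all(mc.apply_fml(cell, 0) == 0 for _ in range(100))

    def test_fml_one_changes_every_site(self):
        fml = np.ones(9)
        mc, cell = cell_with(["io"] * 50, fml=fml)
        assert mc.apply_fml(cell, 3) == 50
        assert not np.any(cell.genome.ops == Genome(["io"]).ops[0])

    def test_mutation_count_matches_binomial_mean(self):
        fml = np.full(9, 0.01)
        fml[0] = 0.0
        mc, cell = cell_with(["nop-a"] * 100, fml=fml)
        n = sum(mc.apply_fml(cell, 1) for _ in range(5000))
        # Binomial(100, 0.01) mean 1.0 per performance
        assert n / 5000 == pytest.approx(1.0, rel=0.1)


class TestRedistribution:
    def _two_cell_mc(self, fml_val=0.5):
        fml = np.full(9, fml_val)
        fml[0] = 0.0
        state, cfg = make_multicell(fml, redistribute=True)
        mc = Multicell(state, cfg, 0)
        a = _grid_cell(mc, 0, 0, ["nop-a"] * 10)
        b = _grid_cell(mc, 1, 0, ["nop-a"] * 10)
        return mc, a, b

    def test_least_loaded_eligible_cell_is_mutated(self):
        mc, a, b = self._two_cell_mc()
        mc.state.ledger[0, b.c] = 3.0
        target = mc.apply_fml_redistributed(1)
        assert target.c == a.c
        assert mc.state.ledger[0, a.c] > 0

    def test_ties_broken_randomly(self):
        hits = set()
        for seed in range(20):
            fml = np.full(9, 0.5)
            fml[0] = 0.0
            state, cfg = make_multicell(fml, seed=seed, redistribute=True)
            mc = Multicell(state, cfg, 0)
            a = _grid_cell(mc, 0, 0, ["nop-a"] * 10)
            b = _grid_cell(mc, 1, 0, ["nop-a"] * 10)
            hits.add(mc.apply_fml_redistributed(1).c)
        assert hits == {0, 1}

    def test_no_eligible_cells_no_mutation(self):
        mc, a, b = self._two_cell_mc()
        a.set_block()
        b.set_block()
        assert mc.apply_fml_redistributed(1) is None

    def test_in_run_policy_ineligible_performer_mutates_itself(self):
        # redistribution redirects only propagule-eligible performers
        mc, a, b = self._two_cell_mc()
        a.set_block()
        machine._apply_fml(mc.state, mc.cfg, 0, a.c, 1)
        assert mc.state.ledger[0, a.c] > 0
        assert mc.state.ledger[0, b.c] == 0.0

    def test_in_run_policy_eligible_performer_redirected(self):
        mc, a, b = self._two_cell_mc()
        mc.state.ledger[0, a.c] = 5.0  # a has worked; b is pristine
        machine._apply_fml(mc.state, mc.cfg, 0, a.c, 1)
        assert mc.state.ledger[0, b.c] > 0.0

    def test_ledgers_stay_balanced_under_redistribution(self):
        mc, a, b = self._two_cell_mc(fml_val=0.001)
        for _ in range(500):
            machine._apply_fml(mc.state, mc.cfg, 0, a.c, 1)
        ledgers = mc.state.ledger[0, [a.c, b.c]]
        per_event = 0.001 * 10
        assert abs(ledgers[0] - ledgers[1]) <= per_event + 1e-12


class TestEligibility:
    def test_set_block_idempotent_and_absorbing(self):
        mc, cell = cell_with(["nop-a"])
        cell.set_block()
        cell.set_block()
        assert not cell.eligible

    def test_block_allowed_false_makes_block_a_noop(self):
        mc, cell = cell_with(["block_propagation"], block_allowed=False)
        cell.run_update()
        assert cell.eligible

    def test_ineligibility_is_absorbing_over_a_whole_trace(self, ancestor):
        # a founder that blocks before its first division: every descendant,
        # over the entire simulation, must remain ineligible
        from germsoma.assays import isolated_run
        from germsoma.instructions import Genome

        founder = Genome(["block_propagation"] + ancestor.names)
        res = isolated_run(founder, 300, seed=3, base_fml=0.0)
        S = res.world.state
        assert S.alive[0].sum() > 1  # it did proliferate
        assert not np.any(S.eligible[0] & S.alive[0])


class TestPropaguleSelection:
    def test_never_returns_ineligible(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            state, cfg = make_multicell(seed=trial)
            mc = Multicell(state, cfg, 0)
            n = rng.integers(1, 26)
            elig_flags = rng.random(n) < 0.5
            for i in range(n):
                _grid_cell(mc, i % 5, i // 5, eligible=bool(elig_flags[i]))
            got = mc.select_propagule(rng)
            if not elig_flags.any():
                assert got is None
            else:
                assert got.eligible

    def test_single_eligible_chosen_with_certainty(self):
        state, cfg = make_multicell()
        mc = Multicell(state, cfg, 0)
        lone = _grid_cell(mc, 2, 2)
        for i in range(5):
            _grid_cell(mc, i, 0, eligible=False)
        rng = np.random.default_rng(1)
        assert all(mc.select_propagule(rng).id == lone.id for _ in range(50))


class TestMessaging:
    def test_broadcast_reaches_all_occupied_neighbours(self):
        state, cfg = make_multicell()
        mc = Multicell(state, cfg, 0)
        sender = _grid_cell(mc, 2, 2)
        for dx, dy in [(-1, -1), (0, -1), (1, -1), (-1, 0),
                       (1, 0), (-1, 1), (0, 1), (1, 1)]:
            _grid_cell(mc, 2 + dx, 2 + dy)
        assert mc.deliver_message(sender, (7, 9), broadcast=True) == 8

    def test_send_to_empty_position_delivers_nothing(self):
        mc, sender = cell_with(["nop-a"])
        assert mc.deliver_message(sender, (1, 2)) == 0

    def test_inbox_overflow_drops_oldest(self):
        state, cfg = make_multicell()
        mc = Multicell(state, cfg, 0)
        sender = _grid_cell(mc, 2, 2)
        sender.facing = 0
        receiver = _grid_cell(mc, 3, 2)
        for i in range(20):
            mc.deliver_message(sender, (i, i))
        box = receiver.inbox
        assert len(box) == 16
        assert box[0] == (4, 4)      # messages 0-3 dropped
        assert box[-1] == (19, 19)


def test_census_frame_schema():
    mc, cell = cell_with(["nop-a"])
    frame = mc.census()
    assert list(frame.columns[:5]) == ["multicell_id", "cell_id", "x", "y",
                                       "eligible"]
    assert "n_NOT" in frame.columns and "workload" in frame.columns
    assert len(frame) == 1
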