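"""Assay procedures: isolated runs, knockouts, aging, lineages, defectors."""

import numpy as np
import pandas as pd
import pytest

from germsoma.assays import (aging_assay, defector_injection, detect_transition,
                             isolated_run, knockout, knockout_assay,
                             line_of_descent, transition_analysis)
from germsoma.instructions import Genome
from germsoma.world import TreatmentConfig, World


class TestIsolatedRun:
    def test_ancestor_acquires_resources(self, ancestor):
        res = isolated_run(ancestor, 300, seed=1)
        assert res.total > 0
        assert len(res.gains) == 300

    def test_pure_nops_acquire_nothing(self):
        res = isolated_run(Genome(["nop-a"] * 20), 200, seed=1)
        assert res.total == 0.0
        assert np.all(res.gains == 0.0)

    def test_same_seed_identical_series(self, ancestor):
        a = isolated_run(ancestor, 150, seed=9)
        b = isolated_run(ancestor, 150, seed=9)
        assert np.array_equal(a.gains, b.gains)

    def test_replication_disabled_tally_unbounded(self, ancestor):
        res = isolated_run(ancestor, 800, seed=1)
        assert res.world.state.tally[0] > 500  # past the threshold, no reset

    def test_rejects_zero_updates(self, ancestor):
        with pytest.raises(ValueError):
            isolated_run(ancestor, 0)


class TestKnockout:
    def test_replaces_every_instance(self):
        g = Genome(["retrieve_message", "io", "retrieve_message", "nand"])
        ko = knockout(g, "retrieve_message")
        assert ko.count("retrieve_message") == 0
        assert ko.count("nop-c") == 2
        assert len(ko) == len(g)
        assert ko[1] == "io" and ko[3] == "nand"

    def test_absent_target_is_identity(self):
        g = Genome(["io", "nand"])
        assert knockout(g, "get_xy") == g

    def test_idempotent(self):
        g = Genome(["get_xy", "io", "get_xy"])
        assert knockout(knockout(g, "get_xy"), "get_xy") == knockout(g, "get_xy")

    def test_commutes_across_distinct_instructions(self):
        g = Genome(["get_xy", "send_message", "io", "get_xy"])
        ab = knockout(knockout(g, "get_xy"), "send_message")
        ba = knockout(knockout(g, "send_message"), "get_xy")
        assert ab == ba

    def test_unknown_instruction_rejected(self):
        with pytest.raises(KeyError):
            knockout(Genome(["io"]), "frobnicate")


class TestKnockoutAssay:
    def test_absent_instruction_ratio_one(self, ancestor):
        res = knockout_assay(ancestor, "broadcast_message", n_updates=200,
                             seed=2, base_fml=0.0)
        assert res["ratio"] == pytest.approx(1.0)
        assert res["baseline"] == res["knockout"]

    def test_nonreplicator_flagged_nan(self):
        res = knockout_assay(Genome(["nop-a"] * 10), "io", n_updates=50, seed=0)
        assert np.isnan(res["ratio"])


class TestAging:
    def test_windows_are_additive(self, ancestor):
        a = aging_assay(ancestor, seed=2, n_updates=1200, young=(0, 500),
                        old=(700, 1200))
        res = a["result"]
        assert a["early_rate"] + a["late_rate"] <= res.total + 1e-9

    def test_nonperformer_flagged_nan(self):
        a = aging_assay(Genome(["nop-a"] * 10), n_updates=200, young=(0, 100),
                        old=(100, 200))
        assert np.isnan(a["relative_rate"])


def _evolved_archive(run_length=1200, **kw):
    cfg = TreatmentConfig(world_size=4, base_fml=0.0, run_length=run_length,
                          seed=13, **kw)
    w = World(cfg)
    w.run(run_length)
    return w


class TestLineOfDescent:
    def test_seed_ancestor_is_length_one(self):
        w = _evolved_archive(run_length=10)
        lineage = line_of_descent(w.archive, 0)
        assert lineage.ids == [0]

    def test_every_lineage_starts_at_a_seed_multicell(self):
        w = _evolved_archive()
        assert w.archive.n_replications > 0
        for mc_id in list(w.archive.records)[-3:]:
            lineage = line_of_descent(w.archive, mc_id)
            assert lineage.ids[0] < 4            # a seeded multicell
            assert lineage.ids[-1] == mc_id
            # founding updates strictly ordered along the chain
            upds = [w.archive.records[i].update for i in lineage.ids]
            assert all(b > a for a, b in zip(upds, upds[1:])) or len(upds) == 1

    def test_offspring_of_seed_is_length_two(self):
        w = _evolved_archive()
        child = next(i for i, r in w.archive.records.items()
                     if 0 <= r.parent_id < 4)
        assert len(line_of_descent(w.archive, child)) == 2

    def test_broken_chain_names_missing_id(self):
        w = _evolved_archive(run_length=10)
        with pytest.raises(KeyError, match="99"):
            line_of_descent(w.archive, 99)

    def test_summaries_schema(self):
        w = _evolved_archive()
        lineage = line_of_descent(w.archive, list(w.archive.records)[-1])
        frame = lineage.compute_summaries(replay_updates=60, seed=1)
        assert list(frame.columns) == ["multicell_id", "ineligible_fraction",
                                       "mean_eligible_workload",
                                       "mean_ineligible_workload"]
        assert len(frame) == len(lineage)


class TestTransition:
    def _step_series(self, n=400, k=180, lo=0.0, hi=0.7, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        s = np.where(np.arange(n) < k, lo, hi)
        return np.clip(s + noise * rng.standard_normal(n), 0, 1)

    def test_recovers_step_position(self):
        for k in (150, 180, 250):
            idx = detect_transition(self._step_series(k=k), window=100)
            assert abs(idx - k) <= 50  # within window/2

    def test_noisy_step_still_recovered(self):
        idx = detect_transition(self._step_series(k=200, noise=0.05), window=100)
        assert abs(idx - 200) <= 50

    def test_constant_series_flagged_no_transition(self):
        assert detect_transition(np.full(400, 0.3), window=100) is None

    def test_pre_post_germ_workload_comparison(self):
        n, k = 400, 180
        frame = pd.DataFrame({
            "ineligible_fraction": self._step_series(n=n, k=k),
            # germ workload drops when the transition happens
            "mean_eligible_workload": np.where(np.arange(n) < k, 8.0, 1.0),
        })
        idx, pre, post = transition_analysis(frame, window=100)
        assert abs(idx - k) <= 50
        assert post < pre

    def test_short_lineage_rejected(self):
        frame = pd.DataFrame({"ineligible_fraction": np.zeros(150),
                              "mean_eligible_workload": np.zeros(150)})
        with pytest.raises(ValueError):
            transition_analysis(frame, window=100)


class TestDefectorInjection:
    def test_full_fraction_initial_frequency_one(self):
        w = _evolved_archive(run_length=60)
        freqs = defector_injection(w, 1.0, follow_updates=5)
        assert freqs[0] == 1.0

    def test_block_knocked_out_and_eligible(self):
        from germsoma.fixtures import build_differentiated_fixture
        from germsoma.assays import isolated_run

        res = isolated_run(build_differentiated_fixture("location"), 150,
                           seed=1, base_fml=0.0)
        w = res.world
        w.replication_enabled = True
        assert w.ineligible_fraction() > 0
        defector_injection(w, 1.0, follow_updates=0)
        S = w.state
        assert w.ineligible_fraction() == 0.0
        block_op = 27
        assert not np.any(S.genome[S.alive] == block_op)

    def test_fraction_out_of_range_rejected(self):
        w = _evolved_archive(run_length=10)
        with pytest.raises(ValueError):
            defector_injection(w, 0.0)

    def test_tags_are_heritable(self):
        w = _evolved_archive(run_length=60)
        freqs = defector_injection(w, 0.5, follow_updates=300)
        assert len(freqs) == 301
        assert np.all((freqs >= 0) & (freqs <= 1))
        assert freqs[-1] > 0  # tagged lineages persist in a neutral setting
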