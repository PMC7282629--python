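"""Trial schedules, participant orchestration, parameter grid."""

import numpy as np
import pytest

from silentwm.experiments import (EXP1_TIMES, EXP2_TIMES, FULL_PLANS,
                                  ParticipantPlan, parameter_grid,
                                  participant_seeds, run_participants,
                                  schedule_exp1, schedule_exp2, schedule_exp3)

from conftest import small_config


def events_of(sched, port):
    return [e for e in sched.events if e.port == port]


class TestSchedules:
    def test_exp1_event_times(self):
        s = schedule_exp1(42.0)
        imps = [e for e in events_of(s, "visual")
                if e.stimulus["kind"] == "impulse"]
        assert all(e.onset_ms == 2150 and e.offset_ms == 2250 for e in imps)
        items = [e for e in events_of(s, "visual") if e.onset_ms == 0]
        assert all(e.offset_ms == 250 for e in items)
        probes = [e for e in events_of(s, "visual") if e.onset_ms == 2650]
        assert len(probes) == 2 and all(e.offset_ms == 2900 for e in probes)
        cue = events_of(s, "reactivation")[0]
        assert (cue.onset_ms, cue.offset_ms) == (1050, 1070)

    def test_exp1_invalid_delta(self):
        with pytest.raises(ValueError):
            schedule_exp1(10.0)

    def test_exp3_soa_zero_has_no_impulse(self):
        s = schedule_exp3(16.0, 0)
        assert not any(e.stimulus["kind"] == "impulse"
                       for e in events_of(s, "visual"))

    def test_exp3_impulse_lasts_until_probe(self):
        for soa in (50, 100, 250, 500):
            s = schedule_exp3(-16.0, soa)
            imp = [e for e in events_of(s, "visual")
                   if e.stimulus["kind"] == "impulse"][0]
            assert imp.offset_ms == 2650
            assert imp.offset_ms - imp.onset_ms == soa

    def test_exp3_shared_cue_and_probe_times(self):
        scheds = [schedule_exp3(16.0, soa) for soa in (0, 50, 100, 250, 500)]
        cues = {events_of(s, "reactivation")[0].onset_ms for s in scheds}
        probes = {e.onset_ms for s in scheds for e in events_of(s, "visual")
                  if e.stimulus["kind"] == "grating" and e.onset_ms > 1000}
        assert cues == {1050}
        assert probes == {2650}

    def test_exp3_invalid(self):
        with pytest.raises(ValueError):
            schedule_exp3(16.0, 75)
        with pytest.raises(ValueError):
            schedule_exp3(12.0, 100)

    def test_exp2_event_times(self):
        s = schedule_exp2(40.0, -16.0)
        vis = events_of(s, "visual")
        probe1 = [e for e in vis if e.module == 0 and e.onset_ms == 1800][0]
        assert probe1.offset_ms == 2050
        react = events_of(s, "reactivation")[0]
        assert react.onset_ms == 1800 + 450  # after the first probe's onset
        assert react.module == 1
        imp2 = [e for e in vis if e.stimulus["kind"] == "impulse"
                and e.onset_ms > 2000][0]
        assert imp2.onset_ms == 1800 + 1750
        probe2 = [e for e in vis if e.module == 1 and e.onset_ms > 3000
                  and e.stimulus["kind"] == "grating"][0]
        assert probe2.onset_ms == 3550 + 100 + 400
        assert s.condition["delta"] == 40.0

    def test_exp2_secondary_input_scaled(self):
        s = schedule_exp2(5.0, 5.0)
        items = [e for e in events_of(s, "visual") if e.onset_ms == 0]
        scales = {e.module: e.stimulus["scale"] for e in items}
        assert scales == {0: 1.0, 1: 0.9}


class TestPlans:
    def test_full_plan_trial_counts(self):
        """30 participants x 1344 trials = 40320 Exp-1 trials; the cell
        structure divides each participant's block evenly."""
        plan_cells = len(ParticipantPlan().cells("exp1"))
        assert plan_cells == 14
        participants, per = FULL_PLANS["exp1"]
        assert participants * per == 40320
        assert per % plan_cells == 0
        assert FULL_PLANS["exp3"] == (20, 280)
        assert FULL_PLANS["exp2"] == (19, 1728)

    def test_exp3_cells(self):
        cells = ParticipantPlan().cells("exp3")
        assert len(cells) == 10  # 5 SOAs x 2 signs
        assert {c["soa_ms"] for c in cells} == {0, 50, 100, 250, 500}

    def test_participant_seeds_stable(self):
        a = participant_seeds(5, 3)
        b = participant_seeds(5, 3)
        assert a == b
        assert len(set(a)) == 3
        assert all(0 <= s < 2**31 for s in a)


@pytest.fixture(scope="module")
def tiny_table():
    cfg = small_config()
    return run_participants("exp1", ParticipantPlan(1, 1), cfg,
                            master_seed=21)


class TestRunParticipants:

    def test_row_count_and_columns(self, tiny_table):
        assert len(tiny_table) == 14
        for col in ("participant", "delta", "response", "correct", "seed"):
            assert col in tiny_table.columns
        assert set(tiny_table.response.unique()).issubset({-1, 1})

    def test_deterministic_given_master_seed(self, tiny_table):
        cfg = small_config()
        again = run_participants("exp1", ParticipantPlan(1, 1), cfg,
                                 master_seed=21)
        assert tiny_table.reset_index(drop=True).equals(
            again.reset_index(drop=True))

    def test_exp2_two_probes_per_trial(self):
        cfg = small_config()

        class TwoCellPlan(ParticipantPlan):
            def cells(self, design, impulse_style="bullseye-black"):
                return [{"delta1_signed": 40.0, "delta2_signed": -16.0},
                        {"delta1_signed": -5.0, "delta2_signed": 24.0}]

        table = run_participants("exp2", TwoCellPlan(1, 1), cfg, master_seed=3)
        assert set(table.probe_index.unique()) == {0, 1}
        assert (table.probe_index == 0).sum() == (table.probe_index == 1).sum()
        # the two probes are judged against their own module's difference
        first = table[table.probe_index == 0].delta.abs().unique()
        second = table[table.probe_index == 1].delta.abs().unique()
        assert set(first) == {40.0, 5.0}
        assert set(second) == {16.0, 24.0}


class TestParameterGrid:
    def test_grid_shape_and_warning(self):
        cfg = small_config()
        plan = ParticipantPlan(1, 1)
        grid = parameter_grid([0.2], [1.5], plan, cfg, master_seed=2)
        assert len(grid) == 1
        assert {"tau_D", "tau_F", "curve"}.issubset(grid.columns)
        with pytest.warns(UserWarning):
            parameter_grid([0.05], [1.5], ParticipantPlan(1, 0), cfg)
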