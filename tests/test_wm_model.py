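"""Two-module architecture: wiring, readouts, reactivation, trial runs."""

import numpy as np
import pytest

from silentwm.config import ModelConfig
from silentwm.stimuli import make_grating
from silentwm.wm_model import (InputEvent, PulseEvent, WMModel, WMModule,
                               angle_difference, apply_reactivation,
                               doubled_angle, run_trial)

from conftest import small_config


class TestArchitecture:
    def test_population_counts(self, model_full):
        mod = model_full.modules[0]
        assert (mod.sensory.n, mod.memory.n, mod.comparison.n,
                mod.decision.n) == (1000, 1500, 1500, 1000)
        assert (mod.sensory.dims, mod.memory.dims, mod.comparison.dims,
                mod.decision.dims) == (24, 24, 4, 1)

    def test_modules_are_independent(self, model_full):
        a, b = model_full.modules
        assert not np.array_equal(a.basis.G, b.basis.G)
        assert not np.array_equal(a.memory.encoders, b.memory.encoders)

    def test_build_determinism(self):
        cfg = small_config()
        a = WMModel(cfg, seed=3, n_modules=1).modules[0]
        b = WMModel(cfg, seed=3, n_modules=1).modules[0]
        np.testing.assert_array_equal(a.dec_mem_ident, b.dec_mem_ident)
        np.testing.assert_array_equal(a.dec_comp_diff, b.dec_comp_diff)

    def test_inconsistent_dimensions_rejected(self):
        cfg = small_config()
        cfg.memory.dims = 12
        with pytest.raises(ValueError):
            WMModel(cfg, seed=0)


class TestOrientationReadout:
    def test_doubled_angle_values(self):
        np.testing.assert_allclose(doubled_angle(0.0), [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(doubled_angle(22.5),
                                   [np.sin(np.pi / 4), np.cos(np.pi / 4)])

    def test_half_turn_maps_to_same_point(self):
        np.testing.assert_allclose(doubled_angle(-90.0), doubled_angle(90.0),
                                   atol=1e-12)

    def test_readout_on_ideal_vectors(self, model_full):
        mod = model_full.modules[0]
        est0 = mod.orientation_readout(mod.basis.ideal_vector(0.0))
        np.testing.assert_allclose(est0, [0.0, 1.0], atol=0.15)
        est225 = mod.orientation_readout(mod.basis.ideal_vector(22.5))
        np.testing.assert_allclose(est225, [0.707, 0.707], atol=0.15)
        a = mod.orientation_readout(mod.basis.ideal_vector(-90.0))
        b = mod.orientation_readout(mod.basis.ideal_vector(90.0))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_angle_difference_formula(self):
        s = doubled_angle(42.0)
        m = doubled_angle(0.0)
        assert np.isclose(angle_difference(s, m), np.sin(np.deg2rad(84.0)))
        assert angle_difference(m, m) == 0.0

    def test_angle_difference_antisymmetric(self, rng):
        a = rng.standard_normal(2)
        b = rng.standard_normal(2)
        assert np.isclose(angle_difference(a, b), -angle_difference(b, a))


class TestReactivation:
    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            apply_reactivation(0, 100, -5, 0.02)

    def test_zero_amplitude_is_noop(self, model_small):
        mod_events = []
        pulses = [PulseEvent(0, 100, 120, 0.0)]
        a = run_trial(model_small, mod_events, pulses, 400, batch=1,
                      modules=[0])
        b = run_trial(model_small, mod_events, [], 400, batch=1, modules=[0])
        np.testing.assert_array_equal(a.modules[0].decision,
                                      b.modules[0].decision)
        np.testing.assert_array_equal(a.modules[0].mem_spike_count,
                                      b.modules[0].mem_spike_count)

    def test_rest_module_pulse_evokes_no_sustained_activity(self, model_full):
        """Without prior facilitation the non-specific pulse is mostly
        subthreshold: a brief nonspecific blip, then silence again."""
        pulses = [PulseEvent(0, 100, 120, 0.02)]
        res = run_trial(model_full, [], pulses, 600, batch=1, modules=[0])
        cnt = res.modules[0].mem_spike_count[0]
        burst = cnt[100:250].sum()
        assert burst < model_full.modules[0].memory.n  # at most a single volley
        assert cnt[400:].sum() == 0  # and silence returns


class TestRunTrial:
    def test_blank_schedule_silent(self, model_small):
        res = run_trial(model_small, [], [], 500, batch=2)
        for tr in res.modules:
            assert tr.mem_spike_count.sum() == 0
            assert tr.sens_spike_count.sum() == 0

    def test_event_beyond_horizon_rejected(self, model_small):
        ev = InputEvent(0, 400, 700, np.zeros((1, 24)))
        with pytest.raises(ValueError):
            run_trial(model_small, [ev], [], 500, batch=1)

    def test_overlapping_events_rejected(self, model_small):
        v = np.zeros((1, 24))
        evs = [InputEvent(0, 0, 100, v), InputEvent(0, 50, 150, v)]
        with pytest.raises(ValueError):
            run_trial(model_small, evs, [], 300, batch=1)

    def test_run_determinism(self, model_small):
        mod = model_small.modules[0]
        v = mod.basis.ideal_vector(10.0)[None]
        evs = [InputEvent(0, 0, 100, v)]
        a = run_trial(model_small, evs, [], 300, batch=2, modules=[0])
        b = run_trial(model_small, evs, [], 300, batch=2, modules=[0])
        np.testing.assert_array_equal(a.modules[0].mem_decoded,
                                      b.modules[0].mem_decoded)

    def test_memory_silent_between_events_full_model(self, model_full):
        """Activity-silence: encoding evokes spiking, the delay does not,
        and the stored item survives in the synaptic state (u elevated)."""
        mod = model_full.modules[0]
        v = mod.basis.ideal_vector(0.0)[None]
        evs = [InputEvent(0, 0, 250, v)]
        res = run_trial(model_full, evs, [], 1600, batch=1, modules=[0])
        tr = res.modules[0]
        assert tr.mem_spike_count[0, :300].sum() > 1000
        assert tr.mem_spike_count[0, 800:1600].sum() == 0
        assert tr.u_mean[0, -1] > 0.25  # calcium trace outlives the spikes
        assert tr.x_mean[0, -1] > 0.95
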