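"""Calcium-kinetics short-term plasticity: jumps, decay, transmission."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silentwm.neural_core import LIFParams, Population, solve_decoders
from silentwm.stsp import (STSPParams, STSPState, efficiency, euler_reference,
                           modulate_spikes, stsp_step)

P = STSPParams()


def run_train(spike_flags, dt=0.001, params=P):
    state = STSPState.rest(1, 1, params)
    for s in spike_flags:
        stsp_step(state, np.array([[bool(s)]]), dt, params)
    return float(state.u[0, 0]), float(state.x[0, 0])


class TestKinetics:
    def test_rest_is_fixed_point(self):
        u, x = run_train([0] * 3000)
        assert np.isclose(u, 0.2, atol=1e-12)
        assert np.isclose(x, 1.0, atol=1e-12)

    def test_single_spike_jump(self):
        """From rest, calcium jumps to 0.36 and resources drop to 0.64."""
        u, x = run_train([1])
        assert abs(u - 0.36) < 1e-6
        assert abs(x - 0.64) < 1e-6

    def test_calcium_relaxation_closed_form(self):
        """1.5 s after a single spike, u = U + (0.36-U) e^{-1} = 0.2589...."""
        u, _ = run_train([1] + [0] * 1500)
        assert abs(u - (0.2 + 0.16 * np.exp(-1.0))) < 1e-6

    def test_resources_recover_with_tau_d(self):
        _, x = run_train([1] + [0] * 200)
        expected = 1.0 - 0.36 * np.exp(-1.0)
        assert abs(x - expected) < 1e-6

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            STSPParams(U=0.0)
        with pytest.raises(ValueError):
            STSPParams(tau_D=-0.1)
        with pytest.raises(ValueError):
            stsp_step(STSPState.rest(1, 1, P), np.zeros((1, 1), bool), 0.0, P)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=400))
    def test_state_bounds_hold(self, train):
        state = STSPState.rest(1, 1, P)
        for s in train:
            stsp_step(state, np.array([[s]]), 0.001, P)
            assert P.U - 1e-12 <= state.u[0, 0] <= 1.0 + 1e-12
            assert -1e-12 <= state.x[0, 0] <= 1.0 + 1e-12

    def test_matches_euler_oracle(self):
        """Exact-exponential stepping at 1 ms equals brute-force Euler at
        0.01 ms over a 20 Hz Poisson train (max deviation < 1e-3)."""
        rng = np.random.default_rng(17)
        train = rng.random(1000) < 0.02  # 1 s at 20 Hz
        state = STSPState.rest(1, 1, P)
        us, xs = [], []
        for s in train:
            stsp_step(state, np.array([[s]]), 0.001, P)
            us.append(state.u[0, 0])
            xs.append(state.x[0, 0])
        u_ref, x_ref = euler_reference(train, 0.001, P, dt_fine=1e-5)
        assert np.max(np.abs(np.array(us) - u_ref)) < 1e-3
        assert np.max(np.abs(np.array(xs) - x_ref)) < 1e-3


class TestEfficiency:
    def test_baseline_is_one(self):
        state = STSPState.rest(1, 4, P)
        np.testing.assert_allclose(efficiency(state, P), 1.0)

    def test_after_single_spike(self):
        state = STSPState.rest(1, 1, P)
        stsp_step(state, np.ones((1, 1), bool), 0.001, P)
        assert abs(efficiency(state, P)[0, 0] - 1.152) < 1e-3

    def test_upper_bound(self):
        state = STSPState(np.ones((1, 3)), np.ones((1, 3)))
        assert np.all(efficiency(state, P) <= 1.0 / P.U + 1e-12)

    def test_release_transmission_monotone_in_calcium(self):
        """A facilitated synapse transmits more per spike than a rested one."""
        rested = STSPState.rest(1, 1, P)
        facilitated = STSPState(np.full((1, 1), 0.55), np.ones((1, 1)))
        r1 = stsp_step(rested, np.ones((1, 1), bool), 0.001, P)
        r2 = stsp_step(facilitated, np.ones((1, 1), bool), 0.001, P)
        assert r2[0, 0] > 1.5 * r1[0, 0]

    def test_depression_then_facilitation_shape(self):
        """After a dense burst the synapse is depressed (release below the
        rested value); once resources recover but calcium is still high it
        is facilitated; eventually it returns to rest."""
        params = P
        probe_release = []
        for gap_ms in (5, 400, 10000):
            state = STSPState.rest(1, 1, params)
            for _ in range(50):  # 250 ms at 200 Hz
                stsp_step(state, np.ones((1, 1), bool), 0.001, params)
                for _ in range(4):
                    stsp_step(state, np.zeros((1, 1), bool), 0.001, params)
            for _ in range(gap_ms):
                stsp_step(state, np.zeros((1, 1), bool), 0.001, params)
            probe_release.append(float(
                stsp_step(state, np.ones((1, 1), bool), 0.001, params)[0, 0]))
        rest_release = params.U * (2 - params.U)
        depressed, facilitated, recovered = probe_release
        assert depressed < rest_release
        assert facilitated > rest_release
        assert abs(recovered - rest_release) < 1e-3


class TestFactoredModulation:
    def test_matches_full_weight_matrix_oracle(self, rng):
        """Row-scaled factored transmission equals the explicit
        w_ij = (release_i / U(2-U)) * w0_ij weight matrix on a toy network."""
        pre = Population(50, 3, LIFParams(), rng=rng)
        post = Population(40, 3, LIFParams(), rng=rng)
        pts = rng.standard_normal((100, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        dec = solve_decoders(pre, pts)  # (3, 50)
        w0 = post.emap @ dec  # (40, 50) full connection weights
        params = P
        state = STSPState.rest(1, pre.n, params)
        rng2 = np.random.default_rng(0)
        rest_rel = params.U * (2 - params.U)
        for _ in range(200):
            spikes = rng2.random((1, pre.n)) < 0.03
            release = stsp_step(state, spikes, 0.001, params)
            # factored path: scale each presynaptic spike, then decode/encode
            factored = ((release / rest_rel) @ dec.T) @ post.emap.T
            # oracle: materialize the modulated weight matrix and apply it
            # to the raw spike vector
            w_eff = w0 * (release[0] / rest_rel)[None, :]
            full = w_eff @ spikes[0].astype(float)
            np.testing.assert_allclose(factored[0], full, atol=1e-10)

    def test_baseline_normalization(self):
        """modulate_spikes scales release by 1/U, matching the
        weight rule w = (u x / U) w0."""
        rel = np.array([[0.36]])
        np.testing.assert_allclose(modulate_spikes(rel, P), rel / P.U)
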