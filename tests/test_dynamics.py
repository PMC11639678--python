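"""LIF layer dynamics: currents, voltages, spikes, thresholds, traces."""

import numpy as np
import pytest

from csdp import NetworkConfig, init_params
from csdp.dynamics import (CircuitState, compute_current, emit_spikes,
                           step_network, step_voltage, update_threshold,
                           update_trace)

from _reference import ref_step_single
from conftest import random_instance


def _cfg(**kw):
    base = dict(layer_sizes=(3, 2), n_classes=2, supervised=True)
    base.update(kw)
    return NetworkConfig(**base)


class TestCurrent:
    def test_zero_spikes_zero_current(self, tiny_cfg, rng):
        params = init_params(tiny_cfg, rng)
        j = compute_current(
            0, np.zeros((1, 6)), np.zeros((1, 4)), np.zeros((1, 5)),
            np.zeros((1, 2)), params, tiny_cfg)
        np.testing.assert_array_equal(j, 0.0)

    def test_single_presynaptic_spike_reads_column(self, tiny_cfg, rng):
        params = init_params(tiny_cfg, rng)
        s_below = np.zeros((1, 6)); s_below[0, 2] = 1.0
        j = compute_current(0, s_below, np.zeros((1, 4)), np.zeros((1, 5)),
                            None, params, tiny_cfg)
        np.testing.assert_allclose(j[0], params.W[0][:, 2])

    def test_lateral_diagonal_never_contributes(self, tiny_cfg, rng):
        params = init_params(tiny_cfg, rng)
        params.M[0][:] = 0.0
        np.fill_diagonal(params.M[0], 7.0)  # arbitrary self weights
        s_self = np.zeros((1, 5)); s_self[0, 1] = 1.0
        j = compute_current(0, np.zeros((1, 6)), np.zeros((1, 4)), s_self,
                            None, params, tiny_cfg)
        np.testing.assert_array_equal(j, 0.0)

    def test_dimension_mismatch_names_bundle(self, tiny_cfg, rng):
        params = init_params(tiny_cfg, rng)
        with pytest.raises(ValueError, match="W"):
            compute_current(0, np.zeros((1, 99)), np.zeros((1, 4)),
                            np.zeros((1, 5)), None, params, tiny_cfg)


class TestVoltage:
    def test_rest_stays_at_rest(self):
        cfg = _cfg()
        np.testing.assert_array_equal(
            step_voltage(np.zeros(3), np.zeros(3), cfg), 0.0)

    def test_dt_equal_tau_m_jumps_to_current(self):
        cfg = _cfg(dt=3.0, tau_m=3.0)
        j = np.array([0.3, -1.2])
        np.testing.assert_allclose(step_voltage(np.array([5.0, -2.0]), j, cfg), j)

    def test_pure_leak(self):
        cfg = _cfg(dt=3.0, tau_m=30.0)
        np.testing.assert_allclose(
            step_voltage(np.array([1.0]), np.array([0.0]), cfg), [0.9])


class TestSpikes:
    def test_threshold_tie_does_not_spike(self):
        s, v = emit_spikes(np.array([1.0, 1.0 + 1e-12]), 1.0)
        np.testing.assert_array_equal(s, [0.0, 1.0])

    def test_spiking_neurons_reset_to_rest(self):
        s, v = emit_spikes(np.array([2.0, 0.0]), 1.0)
        np.testing.assert_array_equal(s, [1.0, 0.0])
        np.testing.assert_array_equal(v, [0.0, 0.0])

    def test_reset_invariant_random_voltages(self, rng):
        v_hat = rng.normal(size=(50, 20))
        s, v = emit_spikes(v_hat, 0.3)
        np.testing.assert_array_equal(v * s, 0.0)


class TestThreshold:
    def test_single_spike_is_equilibrium(self):
        cfg = _cfg()
        s = np.zeros((1, 5)); s[0, 3] = 1.0
        assert update_threshold(0.7, s, cfg) == 0.7

    def test_clipped_at_zero(self):
        cfg = _cfg()
        assert update_threshold(0.0, np.zeros((1, 5)), cfg) == 0.0

    def test_eleven_spikes_hand_value(self):
        cfg = _cfg(lambda_v=0.001)
        s = np.ones((1, 11))
        assert update_threshold(1.0, s, cfg) == pytest.approx(1.01)


class TestTrace:
    def test_silent_trace_stays_zero(self):
        cfg = _cfg()
        np.testing.assert_array_equal(
            update_trace(np.zeros(4), np.zeros(4), cfg), 0.0)

    def test_degenerate_tau_gives_gamma_times_spikes(self):
        cfg = _cfg(dt=3.0, tau_tr=3.0, gamma=0.05)
        s = np.array([1.0, 0.0, 1.0])
        np.testing.assert_allclose(
            update_trace(np.array([0.4, 0.4, 0.0]), s, cfg), cfg.gamma * s)

    def test_fixed_point_of_recurrence(self):
        cfg = _cfg(dt=3.0, tau_tr=6.0, gamma=0.05)  # dt/tau_tr = 0.5
        z = np.array([cfg.gamma])
        np.testing.assert_allclose(
            update_trace(z, np.array([1.0]), cfg), z)


class TestStepNetwork:
    def _drive(self, cfg, rng, batch=1):
        return (rng.random((batch, cfg.layer_sizes[0])) < 0.5).astype(float)

    def test_layer_evaluation_order_is_irrelevant(self, rng):
        cfg = NetworkConfig(layer_sizes=(10, 8, 6, 4), n_classes=3,
                            supervised=True, gamma=0.5, theta_z=1.0,
                            v_thr_init=0.3)
        params = init_params(cfg, rng)
        frames = [self._drive(cfg, rng, 2) for _ in range(50)]
        sy = np.tile([[1.0, 0.0, 0.0]], (2, 1))
        orders = [None, [2, 1, 0], [1, 2, 0]]
        trajectories = []
        for order in orders:
            state = CircuitState.zeros(cfg, 2)
            traj = []
            for f in frames:
                state = step_network(state, f, sy, params, cfg, order=order)
                traj.append((
                    [s.copy() for s in state.spikes],
                    [v.copy() for v in state.voltage],
                    [z.copy() for z in state.trace],
                    state.v_thr.copy(),
                ))
            trajectories.append(traj)
        for other in trajectories[1:]:
            for (sa, va, za, ta), (sb, vb, zb, tb) in zip(trajectories[0], other):
                for a, b in zip(sa + va + za, sb + vb + zb):
                    np.testing.assert_array_equal(a, b)
                np.testing.assert_array_equal(ta, tb)

    def test_zero_input_zero_state_stays_zero(self, tiny_cfg):
        # threshold clips keep the silent network silent indefinitely
        params_rng = np.random.default_rng(0)
        params = init_params(tiny_cfg, params_rng)
        state = CircuitState.zeros(tiny_cfg, 1)
        for _ in range(10):
            state = step_network(
                state, np.zeros((1, 6)), np.zeros((1, 2)), params, tiny_cfg)
        for l in range(tiny_cfg.n_layers):
            assert not state.spikes[l].any()
            assert not state.voltage[l].any()
            assert not state.trace[l].any()

    def test_reset_and_threshold_invariants_along_trajectory(self, rng):
        cfg, params = random_instance(rng)
        state = CircuitState.zeros(cfg, 3)
        for _ in range(20):
            f = self._drive(cfg, rng, 3)
            state = step_network(state, f, None, params, cfg)
            for l in range(cfg.n_layers):
                np.testing.assert_array_equal(
                    state.voltage[l] * state.spikes[l], 0.0)
            assert (state.v_thr >= 0).all()

    def test_matches_scalar_reference_over_steps(self, rng):
        """A 3-layer toy net stepped 5 steps equals the triple-loop oracle."""
        cfg = NetworkConfig(layer_sizes=(4, 3, 3, 2), n_classes=2,
                            supervised=True, gamma=0.3, theta_z=0.7,
                            tau_m=12.0, v_thr_init=0.4)
        params = init_params(cfg, rng)
        state = CircuitState.zeros(cfg, 1)
        ref = {
            "v": [[0.0] * j for j in cfg.layer_sizes[1:]],
            "s": [[0.0] * j for j in cfg.layer_sizes[1:]],
            "z": [[0.0] * j for j in cfg.layer_sizes[1:]],
            "v_thr": [cfg.v_thr_init] * cfg.n_layers,
        }
        sy = [1.0, 0.0]
        for _ in range(5):
            f = self._drive(cfg, rng)
            state = step_network(state, f, np.array([sy]), params, cfg)
            ref = ref_step_single(cfg, params, ref, list(f[0]), sy)
            for l in range(cfg.n_layers):
                np.testing.assert_allclose(state.spikes[l][0], ref["s"][l], atol=0)
                np.testing.assert_allclose(state.voltage[l][0], ref["v"][l],
                                           rtol=1e-12, atol=1e-15)
                np.testing.assert_allclose(state.trace[l][0], ref["z"][l],
                                           rtol=1e-12, atol=1e-15)
                assert state.v_thr[l] == pytest.approx(ref["v_thr"][l], rel=1e-12)
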