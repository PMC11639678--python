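"""Optimizer, initialization, the training loop, and checkpoints."""

import numpy as np
import pytest

from csdp import CSDPClassifier, NetworkConfig, init_params
from csdp.checkpoint import load_checkpoint, save_checkpoint
from csdp.encoding import PatternSet, make_synthetic_dataset
from csdp.optim import Adam
from csdp.params import CircuitParams
from csdp.trainer import (TrainState, run_window, stimulus_steps, train_epoch)


def _cfg(**kw):
    base = dict(layer_sizes=(6, 5, 3), n_classes=2, supervised=True,
                gamma=0.5, theta_z=1.0)
    base.update(kw)
    return NetworkConfig(**base)


class TestAdam:
    def test_zero_gradients_leave_parameters_unchanged(self, rng):
        cfg = _cfg()
        params = init_params(cfg, rng)
        before = params.copy()
        opt = Adam()
        opt.step(params, {"W0": np.zeros_like(params.W[0])})
        np.testing.assert_array_equal(params.W[0], before.W[0])

    def test_clip_ceiling_holds(self):
        cfg = _cfg()
        params = init_params(cfg, np.random.default_rng(0))
        params.W[0][:] = 1.0
        opt = Adam(step_size=0.5)
        opt.step(params, {"W0": -np.ones_like(params.W[0])})  # pushes upward
        assert params.W[0].max() <= 1.0

    def test_matches_textbook_recurrence_three_steps(self):
        # single scalar parameter, hand-iterated adaptive moments
        cfg = NetworkConfig(layer_sizes=(1, 1), n_classes=1, supervised=False)
        params = init_params(cfg, np.random.default_rng(1))
        params.W[0][:] = 0.5
        opt = Adam(step_size=0.01)
        theta, m, v = 0.5, 0.0, 0.0
        for t in range(1, 4):
            g = 0.3 * t
            opt.step(params, {"W0": np.array([[g]])})
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            theta -= 0.01 * (m / (1 - 0.9**t)) / (
                np.sqrt(v / (1 - 0.999**t)) + 1e-8)
            assert params.W[0][0, 0] == pytest.approx(theta, rel=1e-12)

    def test_nonfinite_update_names_bundle(self, rng):
        cfg = _cfg()
        params = init_params(cfg, rng)
        bad = np.full_like(params.M[0], np.nan)
        with pytest.raises(FloatingPointError, match="M0"):
            Adam().step(params, {"M0": bad})


class TestInitParams:
    def test_ranges_and_shapes(self, rng):
        cfg = _cfg(layer_sizes=(6, 5, 3), n_classes=4)
        p = init_params(cfg, rng)
        assert p.W[0].shape == (5, 6) and p.W[1].shape == (3, 5)
        assert p.V[0].shape == (5, 3) and p.V[1] is None
        assert p.M[0].shape == (5, 5) and p.B[0].shape == (5, 4)
        assert p.G[0].shape == (6, 5) and p.A[1].shape == (4, 3)
        assert p.ranges_ok()
        assert p.M[0].min() >= 0.0  # lateral synapses strictly nonnegative

    def test_unsupervised_drops_class_bundles(self, rng):
        p = init_params(_cfg(supervised=False), rng)
        assert all(b is None for b in p.B)

    def test_deterministic_under_seed(self):
        cfg = _cfg()
        a = init_params(cfg, np.random.default_rng(11))
        b = init_params(cfg, np.random.default_rng(11))
        for (na, ma), (nb, mb) in zip(a.items(), b.items()):
            assert na == nb
            np.testing.assert_array_equal(ma, mb)


class TestStimulusSteps:
    @pytest.mark.parametrize("t,expected", [(90.0, 30), (150.0, 50)])
    def test_window_bounds(self, t, expected):
        assert stimulus_steps(_cfg(t_window=t)) == expected

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            stimulus_steps(_cfg(t_window=100.0))


class TestTrainingLoop:
    def test_zero_drive_zero_params_stay_zero(self):
        # lambda_d = 0, zero-initialized synapses, black input: nothing moves
        cfg = _cfg(lambda_d=0.0)
        ts = TrainState.fresh(cfg, np.random.default_rng(0))
        for name, mat in ts.params.items():
            mat[:] = 0.0
        data = PatternSet(np.zeros((6, 6)), np.zeros(6, dtype=int), (2, 3))
        train_epoch(ts, cfg, data, batch_size=3, seed=0, epoch=0)
        for name, mat in ts.params.items():
            np.testing.assert_array_equal(mat, 0.0)

    def test_metric_history_is_deterministic(self):
        ds = make_synthetic_dataset(2, 8, 6, 0.05, rng_seed=3)
        runs = []
        for _ in range(2):
            est = CSDPClassifier(hidden_layer_sizes=(8, 4), n_epochs=2,
                                 batch_size=4, gamma=0.5, theta_z=1.0,
                                 random_state=5)
            est.fit(ds.images, ds.labels)
            runs.append(est.history_)
        assert runs[0] == runs[1]

    def test_positive_goodness_exceeds_negative_after_training(
            self, trained_supervised):
        last = trained_supervised.history_[-1]
        assert last["goodness_pos"] > last["goodness_neg"]

    def test_zeroed_top_down_bundles_still_run(self, rng):
        cfg = _cfg()
        ts = TrainState.fresh(cfg, rng)
        for v in ts.params.V:
            if v is not None:
                v[:] = 0.0
        sensory = (rng.random((3, 6, cfg.t_steps)) < 0.5).astype(float)
        res = run_window(ts, cfg, sensory, None, np.ones(3), learn=False)
        assert np.isfinite(res.loss).all()

    def test_thresholds_persist_across_batches(self):
        ds = make_synthetic_dataset(2, 10, 6, 0.05, rng_seed=3)
        est = CSDPClassifier(hidden_layer_sizes=(8, 4), n_epochs=1,
                             batch_size=5, gamma=0.5, theta_z=1.0,
                             random_state=5)
        est.fit(ds.images, ds.labels)
        assert not np.allclose(est.state_.v_thr, est.config_.v_thr_init)


class TestCheckpoint:
    def test_roundtrip_preserves_model(self, tmp_path, rng):
        cfg = _cfg()
        ts = TrainState.fresh(cfg, rng)
        ts.v_thr[:] = [0.7, 1.3]
        path = tmp_path / "model.h5"
        save_checkpoint(path, ts, cfg)
        ts2, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        np.testing.assert_array_equal(ts2.v_thr, ts.v_thr)
        for (na, ma), (nb, mb) in zip(sorted(ts.params.items()),
                                      sorted(ts2.params.items())):
            assert na == nb
            np.testing.assert_array_equal(ma, mb)


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        est = CSDPClassifier(theta_z=2.5)
        cloned = CSDPClassifier(**est.get_params())
        assert cloned.get_params() == est.get_params()

    def test_sklearn_clone(self):
        from sklearn.base import clone
        est = CSDPClassifier(hidden_layer_sizes=(8,), gamma=0.3)
        assert clone(est).get_params() == est.get_params()

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            CSDPClassifier().predict(np.zeros((1, 4)))

    def test_supervised_fit_requires_labels(self):
        with pytest.raises(ValueError, match="label"):
            CSDPClassifier(supervised=True).fit(np.zeros((4, 4)))

    def test_predict_maps_back_to_original_labels(self):
        ds = make_synthetic_dataset(2, 6, 6, 0.0, rng_seed=1)
        labels = np.where(ds.labels == 0, 10, 42)  # non-contiguous classes
        est = CSDPClassifier(hidden_layer_sizes=(8,), n_epochs=1, batch_size=4,
                             gamma=0.5, theta_z=1.0, random_state=2)
        est.fit(ds.images, labels)
        assert set(est.predict(ds.images)) <= {10, 42}
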