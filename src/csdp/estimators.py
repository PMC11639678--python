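"""Scikit-learn style estimator over the CSDP spiking circuit.

``CSDPClassifier`` wraps the full train/eval machinery behind the familiar
``fit`` / ``predict`` / ``predict_proba`` / ``transform`` surface so the
model composes with sklearn pipelines and model selection. ``X`` rows are
flattened images with intensities in [0, 1]; the estimator Bernoulli-encodes
them into spike trains internally.

The supervised variant clamps class spikes through the B bundles and
contrasts against wrong-label negatives; the unsupervised variant drops B
and contrasts against rotated-mixture negatives. Both train the fast
spiking classifier head (labels touch only those synapses in unsupervised
mode), so both can ``predict``; ``transform`` returns top-layer rate codes
and ``reconstruct`` decodes through the generative head.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .classifier import accuracy as _accuracy
from .config import NetworkConfig
from .negatives import DEFAULT_ETA
from .trainer import (TrainState, evaluate, goodness_scan_classify,
                      train_epoch)


class CSDPClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Recurrent spiking network trained with contrastive signal-dependent
    plasticity.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Widths of the hidden LIF layers.
    supervised : bool
        Whether class-modulation synapses B are present (and negatives are
        wrong-label pairs rather than image mixtures).
    n_epochs, batch_size, learning_rate
        Training-loop constants; defaults follow the reference protocol
        (30 epochs, minibatches of 500, Adam step size 0.002).
    dt, tau_m, tau_tr, gamma, gamma_c, theta_z, lambda_v, lambda_d, r_e,
    r_i, t_window, v_thr_init
        Circuit constants, see :class:`csdp.config.NetworkConfig`.
    eta : float
        Mixture weight for unsupervised negatives.
    image_shape : tuple or None
        (rows, cols) of the input; inferred as square when None (needed for
        the rotation step of unsupervised negatives).
    random_state : int
        Seed for initialization, shuffling, encoding and negative synthesis.

    Attributes
    ----------
    config_ : NetworkConfig
    state_ : TrainState           (synapses, thresholds, optimizer)
    classes_ : ndarray
    history_ : list of dict       per-epoch goodness/loss diagnostics
    """

    def __init__(
        self,
        hidden_layer_sizes: Sequence[int] = (64, 32),
        supervised: bool = True,
        n_epochs: int = 30,
        batch_size: int = 500,
        learning_rate: float = 0.002,
        dt: float = 3.0,
        tau_m: float = 30.0,
        tau_tr: float = 3.0,
        gamma: float = 0.05,
        gamma_c: float = 1.0,
        theta_z: float = 10.0,
        lambda_v: float = 0.001,
        lambda_d: float = 5e-5,
        r_e: float = 1.0,
        r_i: float = 1.0,
        t_window: float = 90.0,
        v_thr_init: float = 1.0,
        eta: float = DEFAULT_ETA,
        image_shape: Optional[Tuple[int, int]] = None,
        random_state: int = 0,
    ) -> None:
        self.hidden_layer_sizes = hidden_layer_sizes
        self.supervised = supervised
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dt = dt
        self.tau_m = tau_m
        self.tau_tr = tau_tr
        self.gamma = gamma
        self.gamma_c = gamma_c
        self.theta_z = theta_z
        self.lambda_v = lambda_v
        self.lambda_d = lambda_d
        self.r_e = r_e
        self.r_i = r_i
        self.t_window = t_window
        self.v_thr_init = v_thr_init
        self.eta = eta
        self.image_shape = image_shape
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _make_config(self, n_pixels: int, n_classes: int) -> NetworkConfig:
        return NetworkConfig(
            layer_sizes=(n_pixels, *tuple(self.hidden_layer_sizes)),
            n_classes=n_classes,
            supervised=self.supervised,
            dt=self.dt, tau_m=self.tau_m, tau_tr=self.tau_tr,
            gamma=self.gamma, gamma_c=self.gamma_c, theta_z=self.theta_z,
            lambda_v=self.lambda_v, lambda_d=self.lambda_d,
            r_e=self.r_e, r_i=self.r_i, t_window=self.t_window,
            v_thr_init=self.v_thr_init,
        )

    def _resolve_shape(self, n_pixels: int) -> Tuple[int, int]:
        if self.image_shape is not None:
            return tuple(self.image_shape)
        side = int(round(np.sqrt(n_pixels)))
        if side * side != n_pixels:
            raise ValueError(
                "image_shape must be given for non-square flattened inputs")
        return (side, side)

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_pixels)")
        if X.size and (X.min() < 0 or X.max() > 1):
            raise ValueError("pixel intensities must lie in [0, 1]")
        return X

    def fit(self, X, y=None) -> "CSDPClassifier":
        """Train the circuit on [0,1] patterns ``X`` with labels ``y``.

        ``y`` may be omitted only in unsupervised mode, in which case the
        classifier head is left untrained and only ``transform`` /
        ``reconstruct`` are meaningful afterwards.
        """
        from .encoding import PatternSet  # local import to avoid cycle at module load

        X = self._validate_X(X)
        if y is None:
            if self.supervised:
                raise ValueError("supervised CSDP requires labels")
            self.classes_ = np.array([], dtype=np.int64)
            labels = None
            n_classes = 1
        else:
            y = np.asarray(y)
            self.classes_, labels = np.unique(y, return_inverse=True)
            n_classes = len(self.classes_)
        self.n_features_in_ = X.shape[1]
        shape = self._resolve_shape(X.shape[1])
        self.config_ = self._make_config(X.shape[1], n_classes)
        rng = np.random.default_rng([int(self.random_state), 0])
        self.state_ = TrainState.fresh(self.config_, rng,
                                       step_size=self.learning_rate)
        data = PatternSet(X, labels, shape)
        self.history_ = []
        for epoch in range(self.n_epochs):
            metrics = train_epoch(
                self.state_, self.config_, data, self.batch_size,
                seed=int(self.random_state), epoch=epoch, eta=self.eta)
            metrics["epoch"] = epoch
            self.history_.append(metrics)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Approximate class posterior: softmaxed classifier spike counts."""
        check_is_fitted(self, "state_")
        X = self._validate_X(X)
        dist, _, _ = evaluate(self.state_, self.config_, X,
                              seed=int(self.random_state))
        return dist

    def predict(self, X) -> np.ndarray:
        """Fast spiking-classifier prediction (no class clamp at test time)."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=-1)]

    def predict_goodness_scan(self, X) -> np.ndarray:
        """Slow classification by per-class goodness scan (supervised only)."""
        check_is_fitted(self, "state_")
        X = self._validate_X(X)
        idx = goodness_scan_classify(self.state_, self.config_, X,
                                     seed=int(self.random_state))
        return self.classes_[idx]

    def transform(self, X) -> np.ndarray:
        """Top-layer rate-code embeddings, one row per sample."""
        check_is_fitted(self, "state_")
        X = self._validate_X(X)
        _, codes, _ = evaluate(self.state_, self.config_, X,
                               seed=int(self.random_state))
        return codes

    def reconstruct(self, X) -> np.ndarray:
        """Decode each pattern through the generative head (no class input)."""
        check_is_fitted(self, "state_")
        X = self._validate_X(X)
        _, _, recon = evaluate(self.state_, self.config_, X,
                               seed=int(self.random_state),
                               collect_recon=True)
        return recon

    def score(self, X, y) -> float:
        """Argmax-agreement accuracy of the fast classifier."""
        proba = self.predict_proba(X)
        y = np.asarray(y)
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        return _accuracy(onehot, proba)

    def save(self, path) -> None:
        """Write synapses, thresholds and config to an HDF5 checkpoint."""
        from .checkpoint import save_checkpoint

        check_is_fitted(self, "state_")
        save_checkpoint(path, self.state_, self.config_)

    @classmethod
    def load(cls, path, classes: Optional[np.ndarray] = None) -> "CSDPClassifier":
        """Rebuild a fitted estimator from a checkpoint."""
        from .checkpoint import load_checkpoint

        ts, cfg = load_checkpoint(path)
        est = cls(
            hidden_layer_sizes=tuple(cfg.layer_sizes[1:]),
            supervised=cfg.supervised, dt=cfg.dt, tau_m=cfg.tau_m,
            tau_tr=cfg.tau_tr, gamma=cfg.gamma, gamma_c=cfg.gamma_c,
            theta_z=cfg.theta_z, lambda_v=cfg.lambda_v, lambda_d=cfg.lambda_d,
            r_e=cfg.r_e, r_i=cfg.r_i, t_window=cfg.t_window,
            v_thr_init=cfg.v_thr_init,
        )
        est.config_ = cfg
        est.state_ = ts
        est.n_features_in_ = cfg.layer_sizes[0]
        est.classes_ = (np.arange(cfg.n_classes) if classes is None
                        else np.asarray(classes))
        est.history_ = []
        return est
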