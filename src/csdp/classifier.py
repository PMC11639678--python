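"""Spiking classifier head and the slow goodness-scan classifier.

The fast head is a single LIF population of C class units driven by the
spikes of *all* hidden layers through per-layer bundles A[l]. Its spike
counts over the stimulus window, softmaxed, approximate the posterior over
classes. The A synapses adapt with an error-driven Hebbian rule against the
clamped label spikes — in unsupervised circuits this is the only place
labels touch plasticity.

The slow alternative clamps each candidate class in turn and picks the one
maximizing time-averaged total goodness; it needs C full simulations per
sample but no extra synapses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.special import softmax

from .config import NetworkConfig
from .dynamics import emit_spikes, step_voltage, update_threshold


@dataclass
class ClassifierState:
    voltage: np.ndarray   # (batch, C)
    spikes: np.ndarray    # (batch, C)
    v_thr: float
    counts: np.ndarray    # (batch, C) accumulated prediction spikes

    @classmethod
    def zeros(cls, cfg: NetworkConfig, batch_size: int,
              v_thr: float = None) -> "ClassifierState":
        c = cfg.n_classes
        return cls(
            voltage=np.zeros((batch_size, c)),
            spikes=np.zeros((batch_size, c)),
            v_thr=cfg.v_thr_init if v_thr is None else float(v_thr),
            counts=np.zeros((batch_size, c)),
        )


def classify_step(
    hidden_spikes: List[np.ndarray],
    A: List[np.ndarray],
    state: ClassifierState,
    cfg: NetworkConfig,
    adapt_thresholds: bool = True,
) -> None:
    """Advance the class units one step from all hidden layers' spikes."""
    drive = cfg.r_e * sum(s @ a.T for s, a in zip(hidden_spikes, A))
    v_hat = step_voltage(state.voltage, drive, cfg)
    s, v = emit_spikes(v_hat, state.v_thr)
    state.voltage = v
    state.spikes = s
    state.counts = state.counts + s
    if adapt_thresholds:
        state.v_thr = update_threshold(state.v_thr, s, cfg)


def classifier_update(pred_spikes: np.ndarray, label_spikes: np.ndarray,
                      hidden_spikes: np.ndarray, r_e: float) -> np.ndarray:
    """dA^l = R_E (mu_y - s_y) s^l^T, batch-averaged, treated as a gradient."""
    n = pred_spikes.shape[0]
    if n == 0:
        return np.zeros((pred_spikes.shape[1], hidden_spikes.shape[1]))
    err = pred_spikes - label_spikes
    return r_e * np.einsum("bc,bj->cj", err, hidden_spikes) / n


def predict_distribution(counts: np.ndarray) -> np.ndarray:
    """Softmax over per-class summed spike counts: the approximate posterior."""
    return softmax(np.atleast_2d(counts), axis=-1)


def accuracy(y_true_onehot: np.ndarray, y_pred_dist: np.ndarray) -> float:
    """Fraction of samples whose argmax prediction matches the argmax label.

    Ties break toward the lowest index (numpy argmax convention).
    """
    y_true_onehot = np.atleast_2d(y_true_onehot)
    y_pred_dist = np.atleast_2d(y_pred_dist)
    if y_true_onehot.shape[0] != y_pred_dist.shape[0]:
        raise ValueError(
            f"row mismatch: {y_true_onehot.shape[0]} labels vs "
            f"{y_pred_dist.shape[0]} predictions"
        )
    return float(
        np.mean(np.argmax(y_true_onehot, axis=-1) == np.argmax(y_pred_dist, axis=-1))
    )


def rate_code(spike_train: np.ndarray, gamma_c: float, t_steps: int) -> np.ndarray:
    """Time-averaged rate embedding c = (gamma_c / T) * sum_t s(t).

    ``spike_train`` is ``(..., J, T_steps)``.
    """
    return (gamma_c / t_steps) * spike_train.sum(axis=-1)
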