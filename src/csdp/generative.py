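"""Local generative head: spiking predictors of the layer below.

Each hidden layer l owns a bundle G[l] that drives a small LIF population
predicting the spikes of layer l-1 (layer 0's predictor reconstructs the
sensory train). Predictor units follow exactly the same leaky dynamics,
strict-threshold emission, gated reset and homeostatic threshold rule as
the main layers; their synapses adapt with an error-driven Hebbian rule on
the mismatch e = s_pred - s_target in {-1, 0, 1}.

Reconstruction averages a clipped activation trace of the bottom predictor's
spikes over the stimulus window; its quality is scored in nats of binary
cross-entropy against the original [0,1] pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .config import NetworkConfig
from .dynamics import emit_spikes, step_voltage, update_threshold

BCE_EPS = 1e-7


@dataclass
class PredictorState:
    """LIF state of the predictors, one per predicted layer 0..L-1."""

    voltage: List[np.ndarray]   # (batch, J_l) for target layer l
    spikes: List[np.ndarray]
    v_thr: np.ndarray           # one scalar per predictor

    @classmethod
    def zeros(cls, cfg: NetworkConfig, batch_size: int,
              v_thr: Optional[np.ndarray] = None) -> "PredictorState":
        sizes = cfg.layer_sizes[:-1]
        thr = (np.full(len(sizes), cfg.v_thr_init) if v_thr is None
               else np.asarray(v_thr, dtype=np.float64).copy())
        return cls(
            voltage=[np.zeros((batch_size, j)) for j in sizes],
            spikes=[np.zeros((batch_size, j)) for j in sizes],
            v_thr=thr,
        )


def predict_layer(
    target: int,
    source_spikes: np.ndarray,
    G: np.ndarray,
    state: PredictorState,
    cfg: NetworkConfig,
    adapt_thresholds: bool = True,
) -> None:
    """Advance the predictor of layer ``target`` one step, in place.

    Driven by R_E * G s_source where the source is layer target+1's
    previous-step spikes.
    """
    if source_spikes.shape[-1] != G.shape[1]:
        raise ValueError(
            f"generative bundle G for layer {target}: source width "
            f"{source_spikes.shape[-1]} != {G.shape[1]}"
        )
    drive = cfg.r_e * (source_spikes @ G.T)
    v_hat = step_voltage(state.voltage[target], drive, cfg)
    s, v = emit_spikes(v_hat, state.v_thr[target])
    state.voltage[target] = v
    state.spikes[target] = s
    if adapt_thresholds:
        state.v_thr[target] = update_threshold(state.v_thr[target], s, cfg)


def mismatch(pred_spikes: np.ndarray, target_spikes: np.ndarray) -> np.ndarray:
    """Error units e = s_pred - s_target, elementwise in {-1, 0, 1}."""
    return pred_spikes - target_spikes


def generative_update(error_below: np.ndarray, spikes: np.ndarray,
                      r_e: float) -> np.ndarray:
    """dG = R_E * e^{l-1} s^l^T, batch-averaged, treated as a gradient."""
    n = error_below.shape[0]
    if n == 0:
        return np.zeros((error_below.shape[1], spikes.shape[1]))
    return r_e * np.einsum("bi,bj->ij", error_below, spikes) / n


def prediction_loss(pred_spikes: np.ndarray, target_spikes: np.ndarray) -> np.ndarray:
    """Per-sample (1/2)||s_pred - s_target||^2, the local objective term."""
    return 0.5 * np.sum(np.square(pred_spikes - target_spikes), axis=-1)


def reconstruction_trace(z: np.ndarray, pred_spikes: np.ndarray,
                         cfg: NetworkConfig) -> np.ndarray:
    """One step of the clipped output trace of the bottom predictor.

    z' = clip(z + (dt/tau_tr)(-z * (1 - s)) + s, 0, 1): the trace jumps a
    full unit on a spike (no gamma factor here) and leaks only where the
    unit is silent; clipping keeps a persistently spiking unit pinned at 1.
    """
    z_new = z + (cfg.dt / cfg.tau_tr) * (-z * (1.0 - pred_spikes)) + pred_spikes
    return np.clip(z_new, 0.0, 1.0)


def reconstruct_from_spikes(pred_spike_train: np.ndarray,
                            cfg: NetworkConfig) -> np.ndarray:
    """x_hat from a bottom-predictor spike train ``(batch, J_0, T_steps)``.

    Runs the clipped trace from rest across the window and averages it:
    x_hat = (1/T) sum_t z(t).
    """
    batch, j0, t_steps = pred_spike_train.shape
    z = np.zeros((batch, j0))
    acc = np.zeros((batch, j0))
    for t in range(t_steps):
        z = reconstruction_trace(z, pred_spike_train[:, :, t], cfg)
        acc += z
    return acc / t_steps


def reconstruction_bce(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Binary cross-entropy in nats, summed over pixels, mean over samples."""
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=np.float64))
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x_hat.shape != x.shape:
        raise ValueError(f"shape mismatch: x_hat {x_hat.shape} vs x {x.shape}")
    q = np.clip(x_hat, BCE_EPS, 1.0 - BCE_EPS)
    per_sample = -np.sum(x * np.log(q) + (1.0 - x) * np.log(1.0 - q), axis=-1)
    return float(per_sample.mean())
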