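"""Leaky integrate-and-fire dynamics for the recurrent circuit.

Every hidden layer is driven, at step t, by the *previous-step* spikes of
its neighbours (bottom-up through W, top-down through V, lateral inhibition
through a hollow-masked M, and optional class modulation through B). Because
a step reads only time-t quantities and writes time-(t+dt) state, all layers
can be evaluated in any order — or fully in parallel — with bit-identical
results; :func:`step_network` exposes the evaluation order to make that
contract testable.

Within one layer the update order is fixed:
current -> voltage -> spikes/reset -> adaptive threshold -> trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .config import NetworkConfig
from .params import CircuitParams


@dataclass
class CircuitState:
    """Dynamic variables of all hidden layers for one batch at one time step.

    Each per-layer entry is ``(batch, J_l)``; ``v_thr`` is one homeostatic
    scalar per layer, shared across the batch.
    """

    current: List[np.ndarray]
    voltage: List[np.ndarray]
    spikes: List[np.ndarray]
    trace: List[np.ndarray]
    v_thr: np.ndarray

    @classmethod
    def zeros(cls, cfg: NetworkConfig, batch_size: int,
              v_thr: Optional[np.ndarray] = None) -> "CircuitState":
        sizes = cfg.layer_sizes[1:]
        mk = lambda j: np.zeros((batch_size, j))
        thr = (np.full(cfg.n_layers, cfg.v_thr_init) if v_thr is None
               else np.asarray(v_thr, dtype=np.float64).copy())
        return cls(
            current=[mk(j) for j in sizes],
            voltage=[mk(j) for j in sizes],
            spikes=[mk(j) for j in sizes],
            trace=[mk(j) for j in sizes],
            v_thr=thr,
        )


def compute_current(
    layer: int,
    s_below: np.ndarray,
    s_above: Optional[np.ndarray],
    s_self: np.ndarray,
    s_class: Optional[np.ndarray],
    params: CircuitParams,
    cfg: NetworkConfig,
) -> np.ndarray:
    """Electrical current into hidden layer ``layer`` (0-based) at time t.

    j = R_E * W s_below + R_E * V s_above - R_I * (M masked hollow) s_self,
    plus R_E * B s_class when class spikes are clamped. The lateral diagonal
    never contributes (no self-inhibition).
    """
    W = params.W[layer]
    if s_below.shape[-1] != W.shape[1]:
        raise ValueError(
            f"bundle W[{layer}]: presynaptic width {s_below.shape[-1]} != {W.shape[1]}"
        )
    j = cfg.r_e * (s_below @ W.T)
    V = params.V[layer]
    if V is not None:
        if s_above is None:
            raise ValueError(f"bundle V[{layer}]: missing spikes from layer above")
        if s_above.shape[-1] != V.shape[1]:
            raise ValueError(
                f"bundle V[{layer}]: presynaptic width {s_above.shape[-1]} != {V.shape[1]}"
            )
        j = j + cfg.r_e * (s_above @ V.T)
    M = params.M[layer]
    if s_self.shape[-1] != M.shape[1]:
        raise ValueError(
            f"bundle M[{layer}]: lateral width {s_self.shape[-1]} != {M.shape[1]}"
        )
    hollow = M * (1.0 - np.eye(M.shape[0]))
    j = j - cfg.r_i * (s_self @ hollow.T)
    if s_class is not None:
        B = params.B[layer]
        if B is None:
            raise ValueError(f"bundle B[{layer}]: class spikes given but no B synapses")
        if s_class.shape[-1] != B.shape[1]:
            raise ValueError(
                f"bundle B[{layer}]: class width {s_class.shape[-1]} != {B.shape[1]}"
            )
        j = j + cfg.r_e * (s_class @ B.T)
    return j


def step_voltage(v: np.ndarray, j: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Candidate membrane voltage: v + (dt/tau_m)(-v + j)."""
    return v + (cfg.dt / cfg.tau_m) * (-v + j)


def emit_spikes(v_hat: np.ndarray, v_thr: float):
    """Strict-threshold spike emission with depolarization reset.

    Returns ``(spikes, voltage)`` where spiking entries (v_hat strictly
    above threshold) reset to the 0 resting potential via binary gating.
    """
    s = (v_hat > v_thr).astype(np.float64)
    return s, v_hat * (1.0 - s)


def update_threshold(v_thr: float, spikes: np.ndarray, cfg: NetworkConfig) -> float:
    """Homeostatic threshold step, clipped nonnegative.

    The increment lambda_v * (sum_j s_j - 1) pushes each layer toward one
    spike per step; for a batch the increment is the batch mean.
    """
    counts = spikes.sum(axis=-1)
    return max(0.0, float(v_thr + cfg.lambda_v * np.mean(counts - 1.0)))


def update_trace(z: np.ndarray, spikes: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Activation-trace low-pass: z + (dt/tau_tr)(-z + gamma * s)."""
    return z + (cfg.dt / cfg.tau_tr) * (-z + cfg.gamma * spikes)


def step_network(
    state: CircuitState,
    sensory_spikes: np.ndarray,
    class_spikes: Optional[np.ndarray],
    params: CircuitParams,
    cfg: NetworkConfig,
    order: Optional[Sequence[int]] = None,
    adapt_thresholds: bool = True,
) -> CircuitState:
    """Advance every hidden layer one step, reading only time-t state.

    ``order`` permutes layer evaluation (default natural order); the result
    is identical for any permutation because new state is written to a fresh
    container and all reads come from ``state``.
    """
    L = cfg.n_layers
    if order is None:
        order = range(L)
    new = CircuitState(
        current=[None] * L, voltage=[None] * L, spikes=[None] * L,
        trace=[None] * L, v_thr=state.v_thr.copy(),
    )
    for l in order:
        s_below = sensory_spikes if l == 0 else state.spikes[l - 1]
        s_above = state.spikes[l + 1] if l + 1 < L else None
        s_class = class_spikes if params.B[l] is not None else None
        j = compute_current(l, s_below, s_above, state.spikes[l], s_class, params, cfg)
        v_hat = step_voltage(state.voltage[l], j, cfg)
        s, v = emit_spikes(v_hat, state.v_thr[l])
        new.current[l] = j
        new.voltage[l] = v
        new.spikes[l] = s
        if adapt_thresholds:
            new.v_thr[l] = update_threshold(state.v_thr[l], s, cfg)
        new.trace[l] = update_trace(state.trace[l], s, cfg)
    return new
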