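"""Contrastive signal-dependent plasticity (CSDP).

Each layer scores its own activity with a *goodness* statistic — the sum of
squared activation traces — and converts it to the probability that the
input is in-distribution via a logistic centred at the threshold theta_z:

    p = sigmoid(sum_k z_k^2 - theta_z)

The per-layer contrastive loss is the binary cross-entropy of p against the
sample tag y_type (1 = real sensory data, 0 = synthesized negative), and the
modulator delta_i = dC/dz_i = 2 z_i (p - y_type) gates four Hebbian-like
synaptic updates. The updates are *gradients of the loss to be minimized*:
flipping their sign silently inverts learning, so they must be handed to a
minimizing optimizer (see :mod:`csdp.optim`).

Every rule is local: layer l's updates read only quantities indexed
l-1, l, l+1 and the class spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.special import expit

from .config import NetworkConfig


def goodness_probability(z: np.ndarray, theta_z: float) -> np.ndarray:
    """p(y_type = 1 | z) = sigmoid(sum_k z_k^2 - theta_z), overflow-safe.

    ``z`` may be ``(J,)`` or ``(batch, J)``; reduction is over the last axis.
    """
    a = np.sum(np.square(z), axis=-1) - theta_z
    return expit(a)


def contrastive_loss(z: np.ndarray, y_type, theta_z: float) -> np.ndarray:
    """Per-layer binary cross-entropy of the goodness probability.

    Computed in logit space, -[y*log p + (1-y)*log(1-p)] = softplus(a) - y*a
    with a = sum z^2 - theta_z, so no log of a saturated sigmoid occurs.
    """
    a = np.sum(np.square(z), axis=-1) - theta_z
    y = np.asarray(y_type, dtype=np.float64)
    return np.logaddexp(0.0, a) - y * a


def modulator(z: np.ndarray, y_type, theta_z: float) -> np.ndarray:
    """delta_i = dC/dz_i = 2 z_i (p - y_type).

    For positives (y_type=1) the factor (p-1) is negative, so descent on the
    loss pushes traces — hence spiking — up; for negatives it pushes down.
    """
    p = goodness_probability(z, theta_z)
    y = np.asarray(y_type, dtype=np.float64)
    return 2.0 * z * (p - y)[..., None]


@dataclass
class UpdateSet:
    """Per-layer synaptic-change tensors, interpreted as gradients.

    ``dV`` is None at the top layer; ``dB`` is None in unsupervised mode.
    """

    dW: np.ndarray
    dV: Optional[np.ndarray]
    dM: np.ndarray
    dB: Optional[np.ndarray]


def _bundle_update(
    lead: float,
    delta: np.ndarray,
    post_spikes: np.ndarray,
    pre_spikes: np.ndarray,
    lambda_d: float,
) -> np.ndarray:
    # lead * delta_i * s_j(pre, t-dt)  +  lambda_d * s_i(t) * (1 - s_j(pre, t-dt))
    n = delta.shape[0]
    hebb = np.einsum("bi,bj->ij", delta, pre_spikes) / n
    decay = np.einsum("bi,bj->ij", post_spikes, 1.0 - pre_spikes) / n
    return lead * hebb + lambda_d * decay


def csdp_updates(
    layer: int,
    delta: np.ndarray,
    spikes: np.ndarray,
    prev_below: np.ndarray,
    prev_above: Optional[np.ndarray],
    prev_self: np.ndarray,
    prev_class: Optional[np.ndarray],
    cfg: NetworkConfig,
) -> UpdateSet:
    """The four CSDP updates for one hidden layer, batch-averaged.

    Presynaptic spikes are previous-step (t - dt) values; the modulator and
    postsynaptic spikes are current-step values. At the first step of a
    window there is no history and the caller passes zero vectors, leaving
    only the decay term where postsynaptic spikes occur.
    """
    dW = _bundle_update(cfg.r_e, delta, spikes, prev_below, cfg.lambda_d)
    dV = (
        _bundle_update(cfg.r_e, delta, spikes, prev_above, cfg.lambda_d)
        if prev_above is not None
        else None
    )
    dM = _bundle_update(cfg.r_i, delta, spikes, prev_self, cfg.lambda_d)
    dB = (
        _bundle_update(cfg.r_e, delta, spikes, prev_class, cfg.lambda_d)
        if prev_class is not None
        else None
    )
    return UpdateSet(dW, dV, dM, dB)


def total_goodness(traces: List[np.ndarray], y_type, theta_z: float) -> np.ndarray:
    """F(t) = sum over layers of the per-layer contrastive loss at time t."""
    return sum(contrastive_loss(z, y_type, theta_z) for z in traces)


def sequence_loss(per_step_totals: List[np.ndarray]) -> np.ndarray:
    """E = sum over the stimulus window of the per-step totals F(t)."""
    return sum(per_step_totals)
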