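"""Simulation and training loops for the full CSDP circuit.

One stimulus window presents a Bernoulli-encoded pattern for ``t_steps``
integration steps. During training, every step computes the CSDP update set
for each hidden layer (modulator and postsynaptic spikes from the current
step, presynaptic spikes from the previous step — zero vectors at the first
step of a window) plus the error-driven head updates, and applies them
immediately through Adam, followed by range truncation. This is online
adaptation within the window, not an end-of-window batch update.

Head updates (generative G, classifier A) are computed on positive samples
only by default: negatives carry deliberately wrong labels and confabulated
images, and training the heads on them would teach the inverse mapping.

Adaptive thresholds are homeostatic, slow state: they persist across
patterns, batches and epochs, and are frozen during evaluation. The fast
variables (current, voltage, spikes, traces, head voltages) reset at each
new pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .classifier import (ClassifierState, classifier_update, classify_step,
                         predict_distribution)
from .config import NetworkConfig
from .dynamics import CircuitState, step_network
from .encoding import PatternSet, encode_bernoulli, encode_labels
from .generative import (PredictorState, generative_update, mismatch,
                         predict_layer, prediction_loss,
                         reconstruct_from_spikes)
from .negatives import DEFAULT_ETA, negative_labels, negative_mixtures
from .optim import Adam
from .params import CircuitParams, init_params
from .plasticity import (contrastive_loss, csdp_updates, goodness_probability,
                         modulator)


def stimulus_steps(cfg: NetworkConfig) -> int:
    """Number of integration steps in the stimulus window (T / dt)."""
    return cfg.t_steps


@dataclass
class TrainState:
    """Everything that persists across stimulus windows."""

    params: CircuitParams
    v_thr: np.ndarray          # per hidden layer
    v_thr_mu: np.ndarray       # per predictor (target layers 0..L-1)
    v_thr_y: float             # classifier head
    optimizer: Adam

    @classmethod
    def fresh(cls, cfg: NetworkConfig, rng: np.random.Generator,
              step_size: float = 0.002) -> "TrainState":
        return cls(
            params=init_params(cfg, rng),
            v_thr=np.full(cfg.n_layers, cfg.v_thr_init),
            v_thr_mu=np.full(cfg.n_layers, cfg.v_thr_init),
            v_thr_y=cfg.v_thr_init,
            optimizer=Adam(step_size=step_size),
        )


@dataclass
class WindowResult:
    """Diagnostics and read-outs from one simulated stimulus window."""

    goodness_p: np.ndarray          # (batch,) time/layer-mean goodness probability
    loss: np.ndarray                # (batch,) summed contrastive loss E
    pred_loss: np.ndarray           # (batch,) summed prediction mismatch loss
    counts: np.ndarray              # (batch, C) classifier spike counts
    top_rate: np.ndarray            # (batch, J_L) top-layer rate code
    goodness_sum: np.ndarray        # (batch,) time-avg sum-of-squared-traces, all layers
    recon: Optional[np.ndarray]     # (batch, J_0) reconstruction, if collected


def run_window(
    ts: TrainState,
    cfg: NetworkConfig,
    sensory: np.ndarray,
    class_clamp: Optional[np.ndarray],
    y_type: np.ndarray,
    label_clamp: Optional[np.ndarray] = None,
    learn: bool = False,
    heads_positive_only: bool = True,
    collect_recon: bool = False,
) -> WindowResult:
    """Simulate one stimulus window for a batch; optionally adapt synapses.

    Parameters
    ----------
    sensory : (batch, J_0, t_steps) binary spike train.
    class_clamp : (batch, C) clamped class spikes driving the B bundles
        (None when no class context is presented).
    y_type : (batch,) 1 for positive samples, 0 for negatives.
    label_clamp : (batch, C) true-label spikes used only as the classifier
        head's teaching signal (may differ from ``class_clamp``, which for
        supervised negatives carries the wrong label).
    learn : master switch for plasticity and threshold adaptation.
    """
    batch, _, t_steps = sensory.shape
    L = cfg.n_layers
    params = ts.params
    state = CircuitState.zeros(cfg, batch, v_thr=ts.v_thr)
    pred = PredictorState.zeros(cfg, batch, v_thr=ts.v_thr_mu)
    cls = ClassifierState.zeros(cfg, batch, v_thr=ts.v_thr_y)
    pos = y_type.astype(bool)

    p_acc = np.zeros(batch)
    loss_acc = np.zeros(batch)
    pred_loss_acc = np.zeros(batch)
    gsum_acc = np.zeros(batch)
    top_count = np.zeros((batch, cfg.layer_sizes[-1]))
    recon_spikes = (
        np.zeros((batch, cfg.layer_sizes[0], t_steps)) if collect_recon else None
    )
    zero_frame = np.zeros((batch, cfg.layer_sizes[0]))
    zero_class = np.zeros((batch, cfg.n_classes))

    for t in range(t_steps):
        frame = sensory[:, :, t]
        prev_frame = sensory[:, :, t - 1] if t > 0 else zero_frame
        prev_class = (class_clamp if t > 0 else zero_class) if class_clamp is not None else None
        prev_hidden = state.spikes  # time-t spikes of every hidden layer

        new = step_network(state, frame, class_clamp, params, cfg,
                           adapt_thresholds=learn)
        for m in range(L):  # predictor of layer m, driven by layer m+1
            predict_layer(m, prev_hidden[m], params.G[m], pred, cfg,
                          adapt_thresholds=learn)
        classify_step(prev_hidden, params.A, cls, cfg, adapt_thresholds=learn)

        if learn:
            grads: Dict[str, np.ndarray] = {}
            for l in range(L):
                delta = modulator(new.trace[l], y_type, cfg.theta_z)
                upd = csdp_updates(
                    l, delta, new.spikes[l],
                    prev_below=prev_frame if l == 0 else prev_hidden[l - 1],
                    prev_above=prev_hidden[l + 1] if l < L - 1 else None,
                    prev_self=prev_hidden[l],
                    prev_class=prev_class if params.B[l] is not None else None,
                    cfg=cfg,
                )
                grads[f"W{l}"] = upd.dW
                if upd.dV is not None:
                    grads[f"V{l}"] = upd.dV
                grads[f"M{l}"] = upd.dM
                if upd.dB is not None:
                    grads[f"B{l}"] = upd.dB
            rows = pos if heads_positive_only else np.ones(batch, bool)
            if rows.any():
                for l in range(L):
                    target = frame if l == 0 else new.spikes[l - 1]
                    err = mismatch(pred.spikes[l], target)
                    grads[f"G{l}"] = generative_update(
                        err[rows], prev_hidden[l][rows], cfg.r_e)
                if label_clamp is not None:
                    for l in range(L):
                        grads[f"A{l}"] = classifier_update(
                            cls.spikes[rows], label_clamp[rows],
                            prev_hidden[l][rows], cfg.r_e)
            ts.optimizer.step(params, grads)

        # per-step diagnostics
        layer_p = np.zeros(batch)
        for l in range(L):
            layer_p += goodness_probability(new.trace[l], cfg.theta_z)
            loss_acc += contrastive_loss(new.trace[l], y_type, cfg.theta_z)
            gsum_acc += np.sum(np.square(new.trace[l]), axis=-1)
        p_acc += layer_p / L
        for m in range(L):
            target = frame if m == 0 else new.spikes[m - 1]
            pred_loss_acc += prediction_loss(pred.spikes[m], target)
        top_count += new.spikes[-1]
        if collect_recon:
            recon_spikes[:, :, t] = pred.spikes[0]
        state = new

    if learn:  # persist the slow homeostatic state
        ts.v_thr = state.v_thr.copy()
        ts.v_thr_mu = pred.v_thr.copy()
        ts.v_thr_y = cls.v_thr

    recon = reconstruct_from_spikes(recon_spikes, cfg) if collect_recon else None
    return WindowResult(
        goodness_p=p_acc / t_steps,
        loss=loss_acc,
        pred_loss=pred_loss_acc,
        counts=cls.counts,
        top_rate=(cfg.gamma_c / t_steps) * top_count,
        goodness_sum=gsum_acc / t_steps,
        recon=recon,
    )


def make_training_batch(
    images: np.ndarray,
    labels: Optional[np.ndarray],
    cfg: NetworkConfig,
    image_shape,
    rng: np.random.Generator,
    eta: float = DEFAULT_ETA,
):
    """Append one synthesized negative per positive and encode spike trains.

    Returns ``(sensory, class_clamp, label_clamp, y_type)`` with the batch
    doubled. Supervised circuits keep the negative images and flip their
    clamped labels; unsupervised circuits mix the negative images and clamp
    no class input.
    """
    n = images.shape[0]
    if cfg.supervised:
        if labels is None:
            raise ValueError("supervised mode needs labels")
        neg_images = images.copy()
        neg_lab = negative_labels(labels, cfg.n_classes, rng)
        class_clamp = np.concatenate(
            [encode_labels(labels, cfg.n_classes),
             encode_labels(neg_lab, cfg.n_classes)])
    else:
        neg_images = negative_mixtures(images, image_shape, rng, eta=eta)
        class_clamp = None
    all_images = np.concatenate([images, neg_images])
    sensory = encode_bernoulli(all_images, cfg.t_steps, rng)
    y_type = np.concatenate([np.ones(n), np.zeros(n)])
    label_clamp = None
    if labels is not None:
        # teaching signal for the classifier head; negative rows repeat the
        # true labels but are excluded from head updates anyway
        lab = encode_labels(labels, cfg.n_classes)
        label_clamp = np.concatenate([lab, lab])
    return sensory, class_clamp, label_clamp, y_type


def train_epoch(
    ts: TrainState,
    cfg: NetworkConfig,
    data: PatternSet,
    batch_size: int,
    seed: int,
    epoch: int,
    eta: float = DEFAULT_ETA,
) -> Dict[str, float]:
    """One pass over the data in shuffled minibatches with appended negatives.

    Returns epoch-mean diagnostics: positive/negative goodness probability,
    contrastive sequence loss, and prediction loss.
    """
    n = len(data)
    shuffle_rng = np.random.default_rng([seed, epoch, 999983])
    order = shuffle_rng.permutation(n)
    n_batches = (n + batch_size - 1) // batch_size
    sums = {"goodness_pos": 0.0, "goodness_neg": 0.0, "loss": 0.0,
            "pred_loss": 0.0}
    count = 0
    for b in range(n_batches):
        idx = order[b * batch_size : (b + 1) * batch_size]
        if cfg.supervised is False and idx.size < 2:
            continue  # mixture negatives need a partner
        rng = np.random.default_rng([seed, epoch * n_batches + b])
        images = data.images[idx]
        labels = data.labels[idx] if data.labels is not None else None
        sensory, class_clamp, label_clamp, y_type = make_training_batch(
            images, labels, cfg, data.image_shape, rng, eta=eta)
        res = run_window(ts, cfg, sensory, class_clamp, y_type,
                         label_clamp=label_clamp, learn=True)
        pos = y_type.astype(bool)
        sums["goodness_pos"] += float(res.goodness_p[pos].sum())
        sums["goodness_neg"] += float(res.goodness_p[~pos].sum())
        sums["loss"] += float(res.loss.sum())
        sums["pred_loss"] += float(res.pred_loss.sum())
        count += idx.size
    return {
        "goodness_pos": sums["goodness_pos"] / count,
        "goodness_neg": sums["goodness_neg"] / count,
        "loss": sums["loss"] / (2 * count),
        "pred_loss": sums["pred_loss"] / (2 * count),
    }


def evaluate(
    ts: TrainState,
    cfg: NetworkConfig,
    images: np.ndarray,
    seed: int,
    batch_size: int = 100,
    collect_recon: bool = False,
):
    """Run plasticity-free windows with no class clamp.

    Returns ``(y_dist, rate_codes, recons)`` — the softmaxed classifier
    posterior, the top-layer rate codes, and reconstructions (or None).
    """
    n = images.shape[0]
    dists, codes, recons = [], [], []
    for b in range(0, n, batch_size):
        chunk = images[b : b + batch_size]
        rng = np.random.default_rng([seed, 31337, b])
        sensory = encode_bernoulli(chunk, cfg.t_steps, rng)
        res = run_window(ts, cfg, sensory, None,
                         np.ones(chunk.shape[0]), learn=False,
                         collect_recon=collect_recon)
        dists.append(predict_distribution(res.counts))
        codes.append(res.top_rate)
        if collect_recon:
            recons.append(res.recon)
    return (
        np.concatenate(dists),
        np.concatenate(codes),
        np.concatenate(recons) if collect_recon else None,
    )


def goodness_scan_classify(
    ts: TrainState,
    cfg: NetworkConfig,
    images: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Slow classifier: clamp each candidate class, pick max mean goodness.

    Supervised circuits only (needs the B bundles). The same encoded spike
    train is reused for every candidate class, so the prediction is a
    deterministic function of the encoding.
    """
    if not cfg.supervised:
        raise ValueError("goodness-scan classification needs class-modulation "
                         "synapses (supervised mode)")
    n = images.shape[0]
    rng = np.random.default_rng([seed, 424242])
    sensory = encode_bernoulli(images, cfg.t_steps, rng)
    scores = np.zeros((n, cfg.n_classes))
    for c in range(cfg.n_classes):
        clamp = encode_labels(np.full(n, c), cfg.n_classes)
        res = run_window(ts, cfg, sensory, clamp, np.ones(n), learn=False)
        scores[:, c] = res.goodness_sum
    return np.argmax(scores, axis=-1)
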