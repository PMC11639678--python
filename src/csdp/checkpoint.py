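"""HDF5 model checkpoints: all synaptic bundles, config, and thresholds."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .config import NetworkConfig
from .optim import Adam
from .params import CircuitParams
from .trainer import TrainState


def save_checkpoint(path, ts: TrainState, cfg: NetworkConfig) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(cfg.to_dict())
        grp = f.create_group("params")
        for name, mat in ts.params.items():
            grp.create_dataset(name, data=mat)
        f.create_dataset("v_thr", data=ts.v_thr)
        f.create_dataset("v_thr_mu", data=ts.v_thr_mu)
        f.attrs["v_thr_y"] = ts.v_thr_y
        f.attrs["adam_step_size"] = ts.optimizer.step_size
        f.attrs["adam_t"] = ts.optimizer.t


def load_checkpoint(path):
    """Load a checkpoint; returns ``(TrainState, NetworkConfig)``.

    Optimizer moments are not persisted — a reloaded model is meant for
    inference or fresh fine-tuning, not for bit-exact training resumption.
    """
    with h5py.File(path, "r") as f:
        cfg = NetworkConfig.from_dict(json.loads(f.attrs["config"]))
        L = cfg.n_layers
        empty = lambda: [None] * L
        params = CircuitParams(empty(), empty(), empty(), empty(), empty(), empty())
        for name in f["params"]:
            params.set(name, f["params"][name][()])
        ts = TrainState(
            params=params,
            v_thr=f["v_thr"][()],
            v_thr_mu=f["v_thr_mu"][()],
            v_thr_y=float(f.attrs["v_thr_y"]),
            optimizer=Adam(step_size=float(f.attrs["adam_step_size"])),
        )
    return ts, cfg
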