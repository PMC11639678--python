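"""Adam optimizer over the circuit's synaptic bundles.

The plasticity rules emit gradients of the objective to be *minimized*; the
optimizer takes an adaptive-moment descent step and then truncates every
bundle back to its declared range ([-1,1], lateral M to [0,1]) — the range
constraint is enforced after every step throughout training.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .params import CircuitParams, _BOUNDS


class Adam:
    """Standard adaptive-moment estimation with bias correction.

    Step size defaults to 0.002; moment decays 0.9 / 0.999, eps 1e-8.
    """

    def __init__(self, step_size: float = 0.002, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.step_size = step_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: CircuitParams, grads: Dict[str, np.ndarray]) -> None:
        """Apply one minimizing step for the named gradients, then clip.

        Bundles absent from ``grads`` are untouched (their moments do not
        decay either: each bundle keeps its own effective schedule aligned
        with the shared step counter via bias correction).
        """
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for name, g in grads.items():
            if g is None:
                continue
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite update for bundle {name}")
            theta = params.get(name)
            if g.shape != theta.shape:
                raise ValueError(
                    f"bundle {name}: update shape {g.shape} != parameter {theta.shape}"
                )
            m = self.m.setdefault(name, np.zeros_like(theta))
            v = self.v.setdefault(name, np.zeros_like(theta))
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            theta -= self.step_size * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
        params.clip_()

    def state_dict(self) -> dict:
        return {
            "step_size": self.step_size, "beta1": self.beta1,
            "beta2": self.beta2, "eps": self.eps, "t": self.t,
            "m": dict(self.m), "v": dict(self.v),
        }
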