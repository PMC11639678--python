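"""Network-wide constants for a CSDP-trained recurrent spiking circuit.

All durations are in milliseconds. A stimulus is presented for a window of
``t_window`` ms, integrated in steps of ``dt`` ms, so a pattern is seen as a
spike train of ``t_steps = t_window / dt`` binary frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass(frozen=True)
class NetworkConfig:
    """Constants governing circuit dynamics and plasticity.

    Parameters
    ----------
    layer_sizes : tuple of int
        ``(J_0, J_1, ..., J_L)`` — the sensory width followed by each hidden
        layer's width. There are ``L = len(layer_sizes) - 1`` hidden layers.
    n_classes : int
        Number of target classes ``C`` (used by the class-modulation and
        classifier synapses even in unsupervised mode).
    supervised : bool
        If True the circuit carries class-modulation synapses B and negatives
        are wrong-label pairs; if False B is absent and negatives are
        rotated-mixture images.
    dt : float
        Integration step (ms).
    tau_m : float
        Membrane time constant (ms). Not pinned by the source model;
        defaults to ``10 * dt``.
    tau_tr : float
        Activation-trace time constant (ms). With ``tau_tr == dt`` the trace
        collapses to ``z = gamma * s`` exactly.
    gamma : float
        Trace increment per spike.
    gamma_c : float
        Rate-code scale for the top-layer embedding.
    theta_z : float
        Goodness threshold: a layer's summed squared traces are compared
        against this value inside a logistic to produce the probability the
        layer assigns to the input being in-distribution.
    lambda_v : float
        Adaptive-threshold step — homeostatic pressure toward one spike per
        layer per step.
    lambda_d : float
        Synaptic decay factor in the plasticity rules.
    r_e, r_i : float
        Excitatory / inhibitory resistances (dimensionless scaling here).
    t_window : float
        Stimulus-presentation window (ms); must divide evenly by ``dt``.
    v_thr_init : float
        Initial adaptive threshold for every layer (and head units).
    """

    layer_sizes: Tuple[int, ...]
    n_classes: int
    supervised: bool = True
    dt: float = 3.0
    tau_m: float = 30.0
    tau_tr: float = 3.0
    gamma: float = 0.05
    gamma_c: float = 1.0
    theta_z: float = 10.0
    lambda_v: float = 0.001
    lambda_d: float = 5e-5
    r_e: float = 1.0
    r_i: float = 1.0
    t_window: float = 90.0
    v_thr_init: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least one hidden layer: layer_sizes = (J_0, J_1, ...)")
        if any(j < 1 for j in self.layer_sizes):
            raise ValueError("all layer sizes must be >= 1")
        for name in ("dt", "tau_m", "tau_tr", "t_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.theta_z <= 0:
            raise ValueError("theta_z must be positive")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")

    @property
    def n_layers(self) -> int:
        """Number of hidden layers L."""
        return len(self.layer_sizes) - 1

    @property
    def t_steps(self) -> int:
        """Number of integration steps in one stimulus window."""
        ratio = self.t_window / self.dt
        steps = round(ratio)
        if abs(ratio - steps) > 1e-9:
            raise ValueError(
                f"t_window={self.t_window} is not an integer multiple of dt={self.dt}"
            )
        return int(steps)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layer_sizes"] = list(self.layer_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["layer_sizes"] = tuple(d["layer_sizes"])
        return cls(**d)
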