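"""Synaptic parameter bundles of the full circuit.

Per hidden layer l (0-based over the L hidden layers):

* ``W[l]`` (J_l x J_{l-1}) — bottom-up drive, range [-1, 1]
* ``V[l]`` (J_l x J_{l+1}) — top-down drive, absent at the top layer
* ``M[l]`` (J_l x J_l)     — lateral inhibition, range [0, 1], hollow in use
* ``B[l]`` (J_l x C)       — class modulation, supervised mode only
* ``G[l]`` (J_{l-1} x J_l) — generative head predicting the layer below
* ``A[l]`` (C x J_l)       — spiking classifier head

Ranges are re-enforced by truncation after every optimizer step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .config import NetworkConfig

# clip range per bundle family
_BOUNDS = {"W": (-1.0, 1.0), "V": (-1.0, 1.0), "M": (0.0, 1.0),
           "B": (-1.0, 1.0), "G": (-1.0, 1.0), "A": (-1.0, 1.0)}


@dataclass
class CircuitParams:
    W: List[np.ndarray]
    V: List[Optional[np.ndarray]]
    M: List[np.ndarray]
    B: List[Optional[np.ndarray]]
    G: List[np.ndarray]
    A: List[np.ndarray]

    def items(self) -> Iterator[Tuple[str, np.ndarray]]:
        """Yield ``(name, matrix)`` for every present bundle, e.g. ('W0', ...)."""
        for fam in ("W", "V", "M", "B", "G", "A"):
            for l, mat in enumerate(getattr(self, fam)):
                if mat is not None:
                    yield f"{fam}{l}", mat

    def get(self, name: str) -> np.ndarray:
        return getattr(self, name[0])[int(name[1:])]

    def set(self, name: str, value: np.ndarray) -> None:
        getattr(self, name[0])[int(name[1:])] = value

    def clip_(self) -> None:
        """Truncate every bundle to its declared range, in place."""
        for name, mat in self.items():
            lo, hi = _BOUNDS[name[0]]
            np.clip(mat, lo, hi, out=mat)

    def copy(self) -> "CircuitParams":
        cp = lambda lst: [None if m is None else m.copy() for m in lst]
        return CircuitParams(cp(self.W), cp(self.V), cp(self.M),
                             cp(self.B), cp(self.G), cp(self.A))

    def ranges_ok(self) -> bool:
        for name, mat in self.items():
            lo, hi = _BOUNDS[name[0]]
            if mat.min() < lo or mat.max() > hi:
                return False
        return True


def init_params(cfg: NetworkConfig, rng: np.random.Generator) -> CircuitParams:
    """Uniform random initialization within each bundle's declared range.

    W, V, B, G, A ~ U(-1, 1); lateral M ~ U(0, 1). In unsupervised mode the
    class-modulation bundles B are absent entirely (not zero-masked).
    """
    sizes = cfg.layer_sizes
    L = cfg.n_layers
    C = cfg.n_classes
    u = lambda shape: rng.uniform(-1.0, 1.0, size=shape)
    W = [u((sizes[l + 1], sizes[l])) for l in range(L)]
    V = [u((sizes[l + 1], sizes[l + 2])) if l < L - 1 else None for l in range(L)]
    M = [rng.uniform(0.0, 1.0, size=(sizes[l + 1], sizes[l + 1])) for l in range(L)]
    B = [u((sizes[l + 1], C)) if cfg.supervised else None for l in range(L)]
    G = [u((sizes[l], sizes[l + 1])) for l in range(L)]
    A = [u((C, sizes[l + 1])) for l in range(L)]
    return CircuitParams(W, V, M, B, G, A)
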