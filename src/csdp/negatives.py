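"""On-the-fly synthesis of negative (out-of-distribution) samples.

Supervised circuits keep the image and pair it with a uniformly drawn wrong
class label. Unsupervised circuits mix each image with a randomly rotated
partner from the same batch: x_neg = eta * x + (1 - eta) * rotate(partner),
with eta = 0.55 and the rotation angle uniform on (pi/4, 7*pi/4).

Exactly one negative is produced per positive; the trainer appends them to
the minibatch (doubling it) with y_type = 0.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage

DEFAULT_ETA = 0.55
ANGLE_RANGE = (np.pi / 4.0, 7.0 * np.pi / 4.0)


def negative_labels(
    labels: np.ndarray, n_classes: int, rng: np.random.Generator
) -> np.ndarray:
    """For each true class c, draw q uniformly from {0..C-1} \\ {c}."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes to draw a wrong label")
    labels = np.asarray(labels, dtype=np.int64)
    # draw in {0..C-2} and shift past the true class to exclude it
    q = rng.integers(0, n_classes - 1, size=labels.shape[0])
    q = q + (q >= labels)
    return q


def rotate_image(flat: np.ndarray, angle_rad: float, image_shape) -> np.ndarray:
    """Rotate one flattened pattern about its centre.

    Bilinear interpolation, zero fill outside the support, clipped to [0,1].
    Kept behind one function so the interpolation policy is pluggable.
    """
    img = flat.reshape(image_shape)
    out = ndimage.rotate(
        img, np.degrees(angle_rad), reshape=False, order=1, mode="constant", cval=0.0
    )
    return np.clip(out, 0.0, 1.0).ravel()


def negative_mixtures(
    batch: np.ndarray,
    image_shape,
    rng: np.random.Generator,
    eta: float = DEFAULT_ETA,
    angle_range: Tuple[float, float] = ANGLE_RANGE,
) -> np.ndarray:
    """Convex mixture of each pattern with a rotated distinct partner."""
    batch = np.asarray(batch, dtype=np.float64)
    n = batch.shape[0]
    if n < 2:
        raise ValueError("mixture negatives need a batch of at least 2 patterns")
    # partner j != i, uniform over the rest of the batch
    partners = rng.integers(0, n - 1, size=n)
    partners = partners + (partners >= np.arange(n))
    angles = rng.uniform(angle_range[0], angle_range[1], size=n)
    out = np.empty_like(batch)
    for i in range(n):
        r = rotate_image(batch[partners[i]], angles[i], image_shape)
        out[i] = eta * batch[i] + (1.0 - eta) * r
    return np.clip(out, 0.0, 1.0)
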