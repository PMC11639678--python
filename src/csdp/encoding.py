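"""Dataset ingestion and spike-train encoding.

Reads IDX-format image/label files (the MNIST / K-MNIST on-disk layout),
normalizes pixel intensities to [0, 1], and converts patterns to Bernoulli
spike trains in which each pixel fires independently per step with
probability equal to its intensity. Labels, when present, are clamped as a
constant one-hot spike vector at every step of the stimulus window.

A synthetic generator produces small class-templated images with the same
container shape so the full pipeline runs without any download.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

IDX_MAGIC_IMAGES = 0x00000803
IDX_MAGIC_LABELS = 0x00000801


class IdxFormatError(ValueError):
    """Raised when an IDX file violates the expected binary layout."""


@dataclass
class PatternSet:
    """A labelled collection of flattened sensory patterns.

    ``images`` is ``(n_samples, n_pixels)`` with values in [0, 1];
    ``labels`` is an integer vector or None; ``image_shape`` is the original
    (rows, cols) so patterns can be reshaped for rotation or display.
    """

    images: np.ndarray
    labels: Optional[np.ndarray]
    image_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 2:
            raise ValueError("images must be 2-D (n_samples, n_pixels)")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("pixel values must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.images.shape[0],):
                raise ValueError("labels must align with images")

    def __len__(self) -> int:
        return self.images.shape[0]


def read_idx(path) -> np.ndarray:
    """Read a single IDX file (images or labels) into a numpy array.

    Images come back as ``(n, rows, cols)`` float64 in [0, 1] (raw / 255);
    labels as ``(n,)`` int64. Malformed files raise :class:`IdxFormatError`
    naming the byte offset of the problem.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise IdxFormatError(f"{path}: truncated header at byte offset 0 (need 4 bytes)")
    (magic,) = struct.unpack(">I", raw[:4])
    if magic == IDX_MAGIC_IMAGES:
        n_dims = 3
    elif magic == IDX_MAGIC_LABELS:
        n_dims = 1
    else:
        raise IdxFormatError(
            f"{path}: bad magic number 0x{magic:08x} at byte offset 0 "
            f"(expected 0x{IDX_MAGIC_IMAGES:08x} images or 0x{IDX_MAGIC_LABELS:08x} labels)"
        )
    header_len = 4 + 4 * n_dims
    if len(raw) < header_len:
        raise IdxFormatError(f"{path}: truncated dimension header at byte offset {len(raw)}")
    dims = struct.unpack(f">{n_dims}I", raw[4:header_len])
    expected = int(np.prod(dims))
    payload = np.frombuffer(raw, dtype=np.uint8, offset=header_len)
    if payload.size != expected:
        raise IdxFormatError(
            f"{path}: payload has {payload.size} bytes at byte offset {header_len}, "
            f"expected {expected} for dims {dims}"
        )
    if magic == IDX_MAGIC_LABELS:
        return payload.astype(np.int64)
    return payload.reshape(dims).astype(np.float64) / 255.0


def read_idx_pair(image_path, label_path) -> PatternSet:
    """Read matching IDX image and label files into a :class:`PatternSet`."""
    images = read_idx(image_path)
    labels = read_idx(label_path)
    if images.ndim != 3:
        raise IdxFormatError(f"{image_path}: expected an image (3-dim) IDX file")
    if labels.ndim != 1:
        raise IdxFormatError(f"{label_path}: expected a label (1-dim) IDX file")
    if images.shape[0] != labels.shape[0]:
        raise IdxFormatError(
            f"image/label count mismatch: {images.shape[0]} vs {labels.shape[0]}"
        )
    n, rows, cols = images.shape
    return PatternSet(images.reshape(n, rows * cols), labels, (rows, cols))


def write_idx_images(path, images: np.ndarray, image_shape: Tuple[int, int]) -> None:
    """Write flattened [0,1] patterns as a uint8 IDX image file."""
    images = np.asarray(images, dtype=np.float64)
    n = images.shape[0]
    rows, cols = image_shape
    data = np.clip(np.round(images * 255.0), 0, 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", IDX_MAGIC_IMAGES, n, rows, cols))
        fh.write(data.tobytes())


def write_idx_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("IDX labels must fit in a byte")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", IDX_MAGIC_LABELS, labels.shape[0]))
        fh.write(labels.astype(np.uint8).tobytes())


def encode_bernoulli(
    pixels: np.ndarray, t_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Encode [0,1] intensities as an independent Bernoulli spike train.

    ``pixels`` may be ``(n_pixels,)`` or ``(batch, n_pixels)``; the result
    gains a trailing time axis of length ``t_steps`` with entries in {0, 1}.
    """
    if t_steps <= 0:
        raise ValueError("t_steps must be positive")
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.size and (pixels.min() < 0 or pixels.max() > 1):
        raise ValueError("pixel intensities must lie in [0, 1]")
    u = rng.random(pixels.shape + (t_steps,))
    return (u < pixels[..., None]).astype(np.float64)


def encode_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot class spikes, clamped (constant) over the window.

    Returns ``(batch, n_classes)``; the trainer broadcasts it across time
    rather than storing T copies.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("labels must lie in {0..C-1}")
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def _class_template(c: int, side: int, rng: np.random.Generator) -> np.ndarray:
    """A distinct binary stroke/blob glyph for class ``c`` on a side×side grid."""
    img = np.zeros((side, side))
    mid = side // 2
    kind = c % 6
    if kind == 0:  # horizontal bar
        img[mid - 1 : mid + 1, 1:-1] = 1.0
    elif kind == 1:  # vertical bar
        img[1:-1, mid - 1 : mid + 1] = 1.0
    elif kind == 2:  # main diagonal stroke
        for k in range(side):
            img[k, max(0, k - 1) : min(side, k + 2)] = 1.0
    elif kind == 3:  # open box
        img[1, 1:-1] = img[-2, 1:-1] = 1.0
        img[1:-1, 1] = img[1:-1, -2] = 1.0
    elif kind == 4:  # cross
        img[mid - 1 : mid + 1, 1:-1] = 1.0
        img[1:-1, mid - 1 : mid + 1] = 1.0
    else:  # filled central blob
        r = max(2, side // 4)
        img[mid - r : mid + r, mid - r : mid + r] = 1.0
    if c >= 6:  # beyond the glyph set: add a seeded random rectangle to stay distinct
        r0, c0 = rng.integers(0, side - 3, size=2)
        h, w = rng.integers(2, max(3, side // 2), size=2)
        img[r0 : r0 + h, c0 : c0 + w] = 1.0 - img[r0 : r0 + h, c0 : c0 + w]
    return img


def make_synthetic_dataset(
    n_classes: int,
    n_per_class: int,
    side: int,
    noise: float,
    rng_seed: int,
) -> PatternSet:
    """Generate a class-templated binary image set with pixel-flip noise.

    Each class has a distinct binary stroke/blob template; every sample is
    the template with each pixel flipped independently with probability
    ``noise``. Deterministic given ``rng_seed``; same container shape as
    :func:`read_idx_pair` output.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if side < 4:
        raise ValueError("side must be >= 4")
    if not (0 <= noise < 1):
        raise ValueError("noise must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    templates = np.stack([_class_template(c, side, rng) for c in range(n_classes)])
    images = np.repeat(templates, n_per_class, axis=0).reshape(-1, side * side)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    flips = rng.random(images.shape) < noise
    images = np.abs(images - flips.astype(np.float64))
    return PatternSet(images, labels, (side, side))


def class_templates(n_classes: int, side: int, rng_seed: int) -> np.ndarray:
    """The noise-free templates underlying :func:`make_synthetic_dataset`."""
    rng = np.random.default_rng(rng_seed)
    return np.stack(
        [_class_template(c, side, rng).ravel() for c in range(n_classes)]
    )
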