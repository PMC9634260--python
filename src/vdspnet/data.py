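"""Synthetic multi-class pattern datasets and IDX-format I/O.

The synthetic generator produces sparse binary prototype images (a
foreground of bright pixels on a zero background, like handwritten digits)
and noisy samples of them.  The zero-valued background occupying most of
each image is structurally important: together with the input-layer bias it
is what lets the plasticity rule depress background synapses, so the
synthetic task exercises the same mechanism as real image data.

The IDX reader/writer handles the container format of the classic MNIST
distribution (big-endian header, magic 0x00000803 for uint8 image tensors
and 0x00000801 for label vectors), so real digit data can be substituted
for the synthetic task when available.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .neurons import ConfigurationError

__all__ = [
    "SyntheticSpec",
    "Dataset",
    "make_prototypes",
    "sample_dataset",
    "read_idx",
    "write_idx",
]

_IDX_IMAGE_MAGIC = 0x00000803
_IDX_LABEL_MAGIC = 0x00000801


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of the synthetic classification task.

    Each class prototype is a ``height x width`` image with 20-40% of its
    pixels set to ``fg_intensity`` and the rest zero; prototypes of distinct
    classes differ in at least 25% of the pixels.  Samples flip each pixel
    independently with probability ``flip_prob`` (foreground to 0,
    background to ``fg_intensity``).
    """

    n_classes: int = 5
    height: int = 10
    width: int = 10
    fg_intensity: int = 255
    flip_prob: float = 0.1
    n_train: int = 3000
    n_test: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least two classes")
        if not (0 <= self.flip_prob < 0.5):
            raise ConfigurationError("flip_prob must lie in [0, 0.5)")
        if not (0 < self.fg_intensity <= 255):
            raise ConfigurationError("fg_intensity must lie in (0, 255]")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass
class Dataset:
    """Image samples with class labels."""

    samples: np.ndarray  # (n, height, width) uint8
    labels: np.ndarray   # (n,) int64
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.samples.shape[0]

    def manifest(self) -> str:
        """JSON manifest describing how the dataset was generated."""
        return json.dumps(
            {
                "n_samples": int(len(self)),
                "shape": list(self.samples.shape[1:]),
                "n_classes": int(np.unique(self.labels).size),
                **self.metadata,
            },
            indent=2,
        )


def make_prototypes(spec: SyntheticSpec, max_tries: int = 200) -> np.ndarray:
    """Class prototype images, deterministic given ``spec.seed``.

    Returns a ``(n_classes, height, width)`` uint8 array.  Foreground
    fractions are drawn uniformly from [0.2, 0.4]; generation retries until
    every pair of prototypes differs in at least 25% of the pixels.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = spec.n_pixels
    min_dist = int(np.ceil(0.25 * n_px))
    for _ in range(max_tries):
        protos = np.zeros((spec.n_classes, n_px), dtype=np.uint8)
        for c in range(spec.n_classes):
            frac = rng.uniform(0.2, 0.4)
            n_fg = int(round(frac * n_px))
            idx = rng.choice(n_px, size=n_fg, replace=False)
            protos[c, idx] = spec.fg_intensity
        binary = protos > 0
        dists = [
            int(np.sum(binary[a] != binary[b]))
            for a in range(spec.n_classes)
            for b in range(a + 1, spec.n_classes)
        ]
        if min(dists) >= min_dist:
            return protos.reshape(spec.n_classes, spec.height, spec.width)
    raise ConfigurationError(
        "could not generate prototypes satisfying the pairwise distance "
        f"constraint after {max_tries} tries"
    )


def _sample_split(
    protos: np.ndarray, spec: SyntheticSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_px = spec.n_pixels
    flat = protos.reshape(spec.n_classes, n_px)
    # balanced labels (within +-1), remainder to the lowest class ids
    per_class = np.full(spec.n_classes, n // spec.n_classes, dtype=np.int64)
    per_class[: n % spec.n_classes] += 1
    labels = np.repeat(np.arange(spec.n_classes), per_class)
    rng.shuffle(labels)
    samples = flat[labels].copy()
    flips = rng.random((n, n_px)) < spec.flip_prob
    fg = samples > 0
    samples[flips & fg] = 0
    samples[flips & ~fg] = spec.fg_intensity
    return samples.reshape(n, spec.height, spec.width), labels


def sample_dataset(spec: SyntheticSpec) -> tuple[Dataset, Dataset]:
    """Generate the (train, test) datasets of the synthetic task.

    Each sample is a class prototype with i.i.d. pixel flips at
    ``flip_prob``; classes are balanced within each split.  Fully
    reproducible from the ``SyntheticSpec`` fields.
    """
    protos = make_prototypes(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    train_x, train_y = _sample_split(protos, spec, spec.n_train, rng)
    test_x, test_y = _sample_split(protos, spec, spec.n_test, rng)
    meta = {"source": "synthetic", "spec": vars(spec)}
    return (
        Dataset(train_x, train_y, {**meta, "split": "train"}),
        Dataset(test_x, test_y, {**meta, "split": "test"}),
    )


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX container (MNIST distribution format).

    Supports the uint8 image tensor (magic 0x00000803, dims
    ``(count, rows, cols)``) and the uint8 label vector (magic 0x00000801).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise IOError(f"{path}: truncated IDX header")
    (magic,) = struct.unpack(">i", raw[:4])
    if magic == _IDX_IMAGE_MAGIC:
        ndim = 3
    elif magic == _IDX_LABEL_MAGIC:
        ndim = 1
    else:
        raise ValueError(f"{path}: unrecognized IDX magic 0x{magic:08x}")
    header = 4 + 4 * ndim
    if len(raw) < header:
        raise IOError(f"{path}: truncated IDX header")
    dims = struct.unpack(f">{ndim}i", raw[4:header])
    expected = int(np.prod(dims))
    payload = np.frombuffer(raw, dtype=np.uint8, offset=header)
    if payload.size != expected:
        raise IOError(
            f"{path}: payload has {payload.size} bytes, header promises {expected}"
        )
    return payload.reshape(dims).copy()


def write_idx(path: str | Path, array: np.ndarray) -> None:
    """Write a uint8 array as an IDX container (3-D images or 1-D labels)."""
    array = np.ascontiguousarray(array, dtype=np.uint8)
    if array.ndim == 3:
        magic = _IDX_IMAGE_MAGIC
    elif array.ndim == 1:
        magic = _IDX_LABEL_MAGIC
    else:
        raise ValueError("IDX writer supports 3-D image or 1-D label arrays")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">i", magic))
        for d in array.shape:
            fh.write(struct.pack(">i", d))
        fh.write(array.tobytes())


def load_idx_dataset(images_path: str | Path, labels_path: str | Path) -> Dataset:
    """Pair an IDX image file with its label file into a Dataset."""
    images = read_idx(images_path)
    labels = read_idx(labels_path).astype(np.int64)
    if images.ndim != 3 or images.shape[0] != labels.shape[0]:
        raise ValueError("image and label files do not describe the same samples")
    return Dataset(
        images,
        labels,
        {"source": "idx", "files": [str(images_path), str(labels_path)]},
    )
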