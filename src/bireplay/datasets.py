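"""Labelled image sets and incremental task protocols.

Three protocol families are supported:

* **split** — the class universe is partitioned into contexts (tasks or
  episodes), each holding a disjoint subset of classes (e.g. five 2-digit
  episodes over ten digit classes);
* **permuted** — every context contains all classes, and each context
  applies a different fixed random permutation to the (zero-padded) pixels;
* **synthetic** — small Gaussian-blob image sets generated on the fly that
  stand in statistically for the handwritten-digit / natural-image datasets
  during development and testing.

Readers for the two standard distribution formats (IDX image/label pairs
and pickled CIFAR-style batches) are provided; all tests run on synthetic
data.
"""

from __future__ import annotations

import json
import pickle
import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabeledImageSet",
    "ContextSpec",
    "TaskProtocol",
    "SyntheticConfig",
    "read_idx",
    "read_cifar_batches",
    "standardize_channels",
    "build_split_protocol",
    "build_permuted_protocol",
    "generate_synthetic_set",
]

SCENARIOS = ("task_il", "domain_il", "class_il")


@dataclass
class LabeledImageSet:
    """Images of shape (n, channels, height, width) with integer labels."""

    images: np.ndarray
    labels: np.ndarray
    split: str = "train"
    class_names: list[str] | None = None
    standardized: bool = False

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError("images must have shape (n, channels, height, width)")
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"image/label count mismatch: {len(self.images)} vs {len(self.labels)}"
            )
        if len(self.labels) and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.images.shape[1:]

    def subset_by_classes(self, class_ids) -> "LabeledImageSet":
        mask = np.isin(self.labels, list(class_ids))
        return LabeledImageSet(
            self.images[mask], self.labels[mask], split=self.split,
            class_names=self.class_names, standardized=self.standardized,
        )


@dataclass
class ContextSpec:
    """One task/episode: its classes and (optional) input transform."""

    context_id: int  # 1-based
    class_ids: tuple[int, ...]
    permutation: np.ndarray | None = None  # flat pixel permutation after padding
    pad_to: int | None = None
    permutation_seed: int | None = None

    def __post_init__(self):
        if self.context_id < 1:
            raise ValueError("context_id is 1-based and must be >= 1")
        self.class_ids = tuple(sorted(int(c) for c in self.class_ids))
        if self.permutation is not None:
            perm = np.asarray(self.permutation)
            if sorted(perm.tolist()) != list(range(len(perm))):
                raise ValueError("permutation must be a bijection on pixel indices")
            self.permutation = perm

    def apply(self, images: np.ndarray) -> np.ndarray:
        """Apply this context's transform (identity or pixel permutation)."""
        if self.permutation is None and self.pad_to is None:
            return images
        n, c, h, w = images.shape
        size = self.pad_to if self.pad_to is not None else h
        if size < h:
            raise ValueError("pad_to smaller than image size")
        pad = size - h
        lo, hi = pad // 2, pad - pad // 2
        out = np.pad(images, ((0, 0), (0, 0), (lo, hi), (lo, hi)))
        if self.permutation is not None:
            flat = out.reshape(n, c, size * size)  # row-major over (height, width)
            flat = flat[:, :, self.permutation]
            out = flat.reshape(n, c, size, size)
        return out


@dataclass
class TaskProtocol:
    """Ordered sequence of contexts plus the scenario they are run under."""

    contexts: list[ContextSpec]
    scenario: str
    n_classes_total: int
    train_set: LabeledImageSet
    test_set: LabeledImageSet
    kind: str = "split"

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.kind == "split":
            all_ids: list[int] = []
            for ctx in self.contexts:
                all_ids.extend(ctx.class_ids)
            if len(all_ids) != len(set(all_ids)):
                raise ValueError("split protocol contexts must have disjoint class sets")

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        img = self.contexts[0].apply(self.train_set.images[:1])
        return img.shape[1:]

    def classes_seen(self, through_context: int) -> tuple[int, ...]:
        """All class ids in contexts 1..through_context (sorted)."""
        ids: set[int] = set()
        for ctx in self.contexts[:through_context]:
            ids.update(ctx.class_ids)
        return tuple(sorted(ids))

    def _data(self, dataset: LabeledImageSet, context_id: int):
        ctx = self.contexts[context_id - 1]
        if self.kind == "split":
            sub = dataset.subset_by_classes(ctx.class_ids)
        else:
            sub = dataset
        return ctx.apply(sub.images), sub.labels

    def train_data(self, context_id: int) -> tuple[np.ndarray, np.ndarray]:
        return self._data(self.train_set, context_id)

    def test_data(self, context_id: int) -> tuple[np.ndarray, np.ndarray]:
        return self._data(self.test_set, context_id)

    def describe(self) -> dict:
        """JSON-serializable description (context ids, classes, perm seeds)."""
        return {
            "kind": self.kind,
            "scenario": self.scenario,
            "n_classes_total": self.n_classes_total,
            "contexts": [
                {
                    "context_id": c.context_id,
                    "class_ids": list(c.class_ids),
                    "pad_to": c.pad_to,
                    "permutation_seed": c.permutation_seed,
                }
                for c in self.contexts
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.describe(), fh, indent=2)


# ---------------------------------------------------------------------------
# readers

def read_idx(image_path, label_path, split: str = "train") -> LabeledImageSet:
    """Read a paired IDX image file and IDX label file (MNIST distribution
    format). Pixel values are scaled to [0, 1]."""
    images = _read_idx_array(image_path, expect_ndim=3)
    labels = _read_idx_array(label_path, expect_ndim=1)
    if images.shape[0] != labels.shape[0]:
        raise ValueError(
            f"image/label count mismatch: {images.shape[0]} vs {labels.shape[0]}"
        )
    imgs = images.astype(np.float64)[:, None, :, :] / 255.0
    return LabeledImageSet(imgs, labels.astype(np.int64), split=split)


def _read_idx_array(path, expect_ndim: int) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(4)
        if len(header) != 4 or header[0] != 0 or header[1] != 0:
            raise ValueError(f"malformed IDX magic number in {path!r}")
        dtype_code, ndim = header[2], header[3]
        dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
                  0x0D: ">f4", 0x0E: ">f8"}
        if dtype_code not in dtypes:
            raise ValueError(f"malformed IDX magic number (dtype 0x{dtype_code:02x})")
        if ndim != expect_ndim:
            raise ValueError(f"expected {expect_ndim}-dimensional IDX file, got {ndim}")
        dims = struct.unpack(">" + "I" * ndim, fh.read(4 * ndim))
        data = np.frombuffer(fh.read(), dtype=dtypes[dtype_code])
    if data.size != int(np.prod(dims)):
        raise ValueError("IDX payload size does not match header dimensions")
    return data.reshape(dims)


def read_cifar_batches(paths, split: str = "train") -> LabeledImageSet:
    """Read pickled CIFAR-style batch files (raw [0,1] pixels; use
    :func:`standardize_channels` afterwards for natural-image mode)."""
    images, labels = [], []
    for path in paths:
        with open(path, "rb") as fh:
            batch = pickle.load(fh, encoding="bytes")
        data = np.asarray(batch[b"data"], dtype=np.float64)
        key = b"labels" if b"labels" in batch else b"fine_labels"
        labels.append(np.asarray(batch[key], dtype=np.int64))
        images.append(data.reshape(-1, 3, 32, 32) / 255.0)
    return LabeledImageSet(np.concatenate(images), np.concatenate(labels), split=split)


def standardize_channels(
    train: LabeledImageSet, test: LabeledImageSet
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Per-channel standardization with statistics from the training split only."""
    mean = train.images.mean(axis=(0, 2, 3), keepdims=True)
    sd = train.images.std(axis=(0, 2, 3), keepdims=True)
    out = []
    for ds in (train, test):
        out.append(
            LabeledImageSet(
                (ds.images - mean) / sd, ds.labels, split=ds.split,
                class_names=ds.class_names, standardized=True,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# protocol builders

def build_split_protocol(
    train: LabeledImageSet,
    test: LabeledImageSet,
    n_contexts: int,
    classes_per_context: int,
    scenario: str = "class_il",
) -> TaskProtocol:
    """Partition the class universe into contexts, in ascending class-id order."""
    needed = n_contexts * classes_per_context
    n_classes = max(train.n_classes, test.n_classes)
    if needed > n_classes:
        raise ValueError(
            f"{n_contexts} contexts x {classes_per_context} classes need {needed} "
            f"classes but the data has {n_classes}"
        )
    contexts = [
        ContextSpec(
            context_id=k + 1,
            class_ids=tuple(range(k * classes_per_context, (k + 1) * classes_per_context)),
        )
        for k in range(n_contexts)
    ]
    return TaskProtocol(contexts, scenario, needed, train, test, kind="split")


def build_permuted_protocol(
    train: LabeledImageSet,
    test: LabeledImageSet,
    n_contexts: int,
    pad_to: int | None = None,
    seed: int = 0,
    scenario: str = "domain_il",
) -> TaskProtocol:
    """Each context applies a distinct seeded pixel permutation (after
    zero-padding to `pad_to`); every context is a full n-way problem."""
    h = train.images.shape[2]
    size = pad_to if pad_to is not None else h
    if size < h:
        raise ValueError("pad_to must be >= image size")
    contexts = []
    for k in range(1, n_contexts + 1):
        sub_seed = seed + k  # context k uses master seed + k
        rng = np.random.default_rng(sub_seed)
        perm = rng.permutation(size * size)
        contexts.append(
            ContextSpec(
                context_id=k,
                class_ids=tuple(range(train.n_classes)),
                permutation=perm,
                pad_to=size,
                permutation_seed=sub_seed,
            )
        )
    return TaskProtocol(contexts, scenario, train.n_classes, train, test, kind="permuted")


# ---------------------------------------------------------------------------
# synthetic data

@dataclass
class SyntheticConfig:
    """Configuration for the Gaussian-blob synthetic image generator.

    Each class c has a fixed spatial template ``0.5 + class_separation * U_c``
    with ``U_c`` a seeded standard-normal pattern; images are the template
    plus independent pixel noise, clipped to [0, 1].  ``class_separation``
    controls how far apart class means sit in pixel space and ``noise_sd``
    the within-class spread, so (separation, noise) together set the
    difficulty of the classification problem much as digit identity vs
    handwriting variability do for handwritten-digit data.
    """

    n_classes: int = 10
    images_per_class_train: int = 100
    images_per_class_test: int = 50
    image_size: int = 8
    channels: int = 1
    class_separation: float = 0.25
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_classes", "images_per_class_train", "images_per_class_test",
                     "image_size", "channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.class_separation < 0 or self.noise_sd < 0:
            raise ValueError("class_separation and noise_sd must be nonnegative")


def generate_synthetic_set(
    config: SyntheticConfig,
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Generate a (train, test) pair of synthetic labelled image sets.

    Deterministic given ``config.seed``; train and test are disjoint draws
    around the same class templates.
    """
    rng = np.random.default_rng(config.seed)
    c, s = config.channels, config.image_size
    templates = 0.5 + config.class_separation * rng.standard_normal(
        (config.n_classes, c, s, s)
    )
    out = []
    for n_per, split in (
        (config.images_per_class_train, "train"),
        (config.images_per_class_test, "test"),
    ):
        images = np.empty((config.n_classes * n_per, c, s, s))
        labels = np.empty(config.n_classes * n_per, dtype=np.int64)
        for cls in range(config.n_classes):
            noise = config.noise_sd * rng.standard_normal((n_per, c, s, s))
            images[cls * n_per : (cls + 1) * n_per] = templates[cls] + noise
            labels[cls * n_per : (cls + 1) * n_per] = cls
        np.clip(images, 0.0, 1.0, out=images)
        out.append(LabeledImageSet(images, labels, split=split))
    return out[0], out[1]
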