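"""Embedding backbones and image providers.

The default backbone is a small two-layer perceptron over standardized,
flattened images, followed by an encoding layer that reduces the feature
dimensionality (average pooling by default, a learned fully connected map as
the alternative).  Any object with ``embed(images) -> (n, D) array`` and the
``output_dim`` / ``input_size`` attributes satisfies the backbone contract, so
stronger feature extractors can be plugged in without touching the methods.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass(frozen=True)
class EncodingConfig:
    """Encoding layer reducing backbone features to ``output_size`` dims."""

    kind: str = "average-pooling"  # or "fully-connected"
    output_size: int = 128

    def __post_init__(self) -> None:
        if self.kind not in ("average-pooling", "fully-connected"):
            raise ValueError(f"unknown encoding kind {self.kind!r}")
        if self.output_size < 1:
            raise ValueError("output_size must be >= 1")


def preprocess(images: np.ndarray) -> np.ndarray:
    """Standardize each image to zero mean / unit sd and flatten.

    Accepts ``(n, h, w)`` or ``(n, h, w, 3)`` arrays; RGB is collapsed to
    grayscale by channel averaging.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 4:
        images = images.mean(axis=-1)
    if images.ndim != 3:
        raise ValueError("expected a batch of 2-D images")
    flat = images.reshape(len(images), -1)
    mean = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    return (flat - mean) / np.maximum(sd, 1e-8)


class MLPBackbone:
    """Small convolutional-style embedder: pooling stem plus trainable layers.

    The stem is a fixed stride-``patch_size`` average-pooling convolution that
    collapses each patch to its mean — local spatial pooling that lifts the
    signal-to-noise ratio of localized structure the way the early strided
    layers of a convnet do.  Two trainable fully connected layers with ReLU
    follow, then the encoding layer reduces dimensionality.  Produces
    ``encoding.output_size``-dimensional embeddings.  Deterministic in
    evaluation mode (``embed``); ``forward`` builds an autodiff graph for
    training.
    """

    def __init__(
        self,
        input_size: int = 64,
        patch_size: int = 4,
        hidden_dim: int = 512,
        feature_dim: int = 256,
        encoding: EncodingConfig = EncodingConfig(),
        init: str = "looks-linear",
        seed: int = 0,
        trainable: bool = True,
    ):
        if encoding.kind == "average-pooling" and feature_dim % encoding.output_size:
            raise ValueError(
                f"average pooling needs feature_dim ({feature_dim}) divisible "
                f"by output_size ({encoding.output_size})"
            )
        if input_size % patch_size:
            raise ValueError(
                f"input_size ({input_size}) must be divisible by "
                f"patch_size ({patch_size})"
            )
        self.input_size = input_size
        self.patch_size = patch_size
        self.hidden_dim = hidden_dim
        self.feature_dim = feature_dim
        self.encoding = encoding
        self.trainable = trainable
        if init not in ("looks-linear", "he"):
            raise ValueError(f"unknown init scheme {init!r}")
        self.init = init
        grid = input_size // patch_size
        d_in = grid * grid
        rng = np.random.default_rng(seed)

        def he(fan_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        if init == "looks-linear":
            # Mirrored-identity ("looks-linear") initialization: the first
            # layer computes [relu(x), relu(-x)] blocks and the second
            # recombines them as relu(x) - relu(-x) = x, so the untrained
            # network is the identity on the pooled-patch features and
            # training refines an informative embedding instead of scrambling
            # it.  Small noise breaks exact symmetry.
            w1 = np.zeros((d_in, hidden_dim))
            for k in range(hidden_dim):
                w1[k % d_in, k] = 1.0 if (k // d_in) % 2 == 0 else -1.0
            w2 = np.zeros((hidden_dim, feature_dim))
            repeats = np.zeros(feature_dim)
            for k in range(hidden_dim):
                j = k % feature_dim
                w2[k, j] = 1.0 if (k // d_in) % 2 == 0 else -1.0
                repeats[j] += 0.5
            w2 /= np.maximum(repeats, 1.0)[None, :]
            self.W1 = Tensor(w1 + 0.01 * he(d_in, w1.shape), requires_grad=True)
            self.W2 = Tensor(
                w2 + 0.01 * he(hidden_dim, w2.shape), requires_grad=True
            )
        else:
            self.W1 = Tensor(he(d_in, (d_in, hidden_dim)), requires_grad=True)
            self.W2 = Tensor(
                he(hidden_dim, (hidden_dim, feature_dim)), requires_grad=True
            )
        self.b1 = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.b2 = Tensor(np.zeros(feature_dim), requires_grad=True)
        if encoding.kind == "fully-connected":
            self.We = Tensor(
                he(feature_dim, (feature_dim, encoding.output_size)),
                requires_grad=True,
            )
            self.be = Tensor(np.zeros(encoding.output_size), requires_grad=True)
            self._pool = None
        else:
            self.We = self.be = None
            group = feature_dim // encoding.output_size
            pool = np.zeros((feature_dim, encoding.output_size))
            for j in range(encoding.output_size):
                pool[j * group : (j + 1) * group, j] = 1.0 / group
            self._pool = pool

    @property
    def output_dim(self) -> int:
        return self.encoding.output_size

    def parameters(self) -> list[Tensor]:
        params = [self.W1, self.b1, self.W2, self.b2]
        if self.We is not None:
            params += [self.We, self.be]
        return params

    def _stem(self, images: np.ndarray) -> np.ndarray:
        """Standardize, then stride-p average-pool to a flattened patch grid."""
        flat = preprocess(images)
        n = len(flat)
        s, p = self.input_size, self.patch_size
        if flat.shape[1] != s * s:
            raise ValueError(
                f"expected {s}x{s} images, got {flat.shape[1]} pixels"
            )
        grid = s // p
        pooled = flat.reshape(n, grid, p, grid, p).mean(axis=(2, 4))
        return pooled.reshape(n, grid * grid)

    def forward(self, images: np.ndarray) -> Tensor:
        """Embed a batch, building the autodiff graph."""
        x = self._stem(images)
        h = ad.relu(ad.add(ad.matmul(Tensor(x), self.W1), self.b1))
        # Linear output layer: keeps the mirrored-identity reconstruction
        # exact at init and the embedding space signed.
        feats = ad.add(ad.matmul(h, self.W2), self.b2)
        if self._pool is not None:
            return ad.matmul(feats, Tensor(self._pool))
        return ad.add(ad.matmul(feats, self.We), self.be)

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Embed a batch without building a graph (evaluation mode)."""
        return self.forward(images).data

    def checksum(self) -> str:
        """Exact digest of all parameter values (frozen-backbone contract)."""
        digest = hashlib.sha256()
        for p in self.parameters():
            digest.update(np.ascontiguousarray(p.data).tobytes())
        return digest.hexdigest()


class FileImageLoader:
    """Image provider reading PNG/JPEG files from ``record.image_path``.

    Resizes with Lanczos resampling to ``input_size`` and returns grayscale
    float arrays.
    """

    def __init__(self, input_size: int = 64):
        self.input_size = input_size
        self.image_size = input_size

    def __call__(self, record) -> np.ndarray:
        from PIL import Image

        if not record.image_path:
            raise FileNotFoundError(f"record {record.id!r} has no image_path")
        with Image.open(record.image_path) as img:
            img = img.convert("L").resize(
                (self.input_size, self.input_size), Image.LANCZOS
            )
            return np.asarray(img, dtype=np.float32)

    def batch(self, table, record_ids) -> np.ndarray:
        rows = table.rows_for_ids(record_ids)
        return np.stack([self(table.record(i)) for i in rows])
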