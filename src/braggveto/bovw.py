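"""Bag-of-visual-words encoding of ORB descriptors.

Each frame is summarised by a histogram over a small codebook of "visual
words" — cluster centres learned by mini-batch K-means over the pooled
binary descriptors of a training set.  The sizing follows the pipeline's
fixed rules: ``k = 5 * n_classes`` clusters, batch size ``b = S / 3``
(``S`` = total descriptor count) and K-means++ initialisation on an
``init_size = 3 * b`` subsample.  The 256-bit descriptors are relaxed to
0/1 real vectors so Euclidean K-means applies; squared Euclidean distance
on bit vectors equals Hamming distance, so the relaxation preserves the
descriptor geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import MiniBatchKMeans
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class BoVWConfig:
    """Codebook sizing: k = 5 * n_classes; b = S/3; init_size = 3b."""

    n_classes: int = 2
    max_iterations: int = 100
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")

    @property
    def n_clusters(self) -> int:
        return 5 * self.n_classes


@dataclass
class Codebook:
    """Learned visual words: ``centers`` is (k, n_bits) real-valued."""

    centers: np.ndarray
    config: BoVWConfig
    training_descriptor_count: int

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def unpack_descriptors(descriptors: np.ndarray) -> np.ndarray:
    """Packed uint8 (n, n_bits/8) -> float32 0/1 matrix (n, n_bits)."""
    d = np.asarray(descriptors, dtype=np.uint8).reshape(len(descriptors), -1)
    return np.unpackbits(d, axis=1).astype(np.float32)


def _pool(descriptor_lists: Sequence[np.ndarray]) -> np.ndarray:
    nonempty = [np.asarray(d) for d in descriptor_lists if len(d)]
    if not nonempty:
        raise ValueError("no descriptors to pool")
    return np.concatenate(nonempty, axis=0)


def fit_codebook(descriptors: np.ndarray, config: BoVWConfig) -> Codebook:
    """Cluster pooled descriptors into the visual-word codebook.

    ``descriptors`` may be packed uint8 or already-unpacked 0/1 vectors.
    Mini-batch K-means with batch size S/3, K-means++ init on a 3b = S
    subsample, stopping at ``max_iterations`` batches or centre movement
    below ``tol``; fully determined by ``config.seed``.
    """
    X = np.asarray(descriptors)
    if X.dtype == np.uint8 and X.shape[1] * 8 >= config.n_clusters:
        X = unpack_descriptors(X)
    X = X.astype(np.float32, copy=False)
    S = X.shape[0]
    b = max(S // 3, 1)
    init_size = min(3 * b, S)
    if S < config.n_clusters or init_size < config.n_clusters:
        raise ValueError(
            f"{S} descriptors are too few for a {config.n_clusters}-word codebook "
            f"(init subsample {init_size}); supply more data or fewer classes"
        )
    km = MiniBatchKMeans(
        n_clusters=config.n_clusters,
        init="k-means++",
        batch_size=b,
        init_size=init_size,
        max_iter=config.max_iterations,
        tol=config.tol,
        max_no_improvement=None,
        n_init=1,
        random_state=config.seed,
    )
    km.fit(X)
    return Codebook(
        centers=km.cluster_centers_.astype(np.float64),
        config=config,
        training_descriptor_count=S,
    )


def assign_words(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Index of the nearest centre for each descriptor (ties: lowest index)."""
    if len(descriptors) == 0:
        return np.empty(0, dtype=int)
    X = np.asarray(descriptors)
    if X.dtype == np.uint8:
        X = unpack_descriptors(X)
    X = X.astype(np.float64, copy=False)
    C = codebook.centers
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; argmin over centres
    d2 = (X**2).sum(axis=1)[:, None] - 2.0 * X @ C.T + (C**2).sum(axis=1)[None, :]
    return np.argmin(d2, axis=1)


def encode(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Histogram of visual-word counts for one frame (length k, ints)."""
    words = assign_words(descriptors, codebook)
    return np.bincount(words, minlength=codebook.n_clusters).astype(np.int64)


def encode_dataset(
    descriptor_lists: Sequence[np.ndarray],
    codebook: Codebook,
    normalize: bool = True,
) -> np.ndarray:
    """Feature matrix with one histogram row per frame.

    With ``normalize`` (default) counts become frequencies: each row is
    divided by max(total, 1), so descriptor-free frames stay all-zero.
    """
    rows = np.stack([encode(d, codebook) for d in descriptor_lists]).astype(np.float64)
    if normalize:
        totals = rows.sum(axis=1, keepdims=True)
        rows = rows / np.maximum(totals, 1.0)
    return rows


class BovwEncoder(TransformerMixin, BaseEstimator):
    """Transformer: per-frame descriptor arrays -> (n_frames, k) features.

    ``fit`` pools the per-frame descriptors and learns the codebook
    (``codebook_``); ``transform`` encodes each frame as a (normalised)
    visual-word histogram.  The feature dimension equals the codebook
    size ``5 * n_classes``, which is also the downstream classifier's
    input width.
    """

    def __init__(
        self,
        n_classes: int = 2,
        max_iterations: int = 100,
        tol: float = 1e-4,
        normalize: bool = True,
        random_state: int = 0,
    ):
        self.n_classes = n_classes
        self.max_iterations = max_iterations
        self.tol = tol
        self.normalize = normalize
        self.random_state = random_state

    def fit(self, X: Sequence[np.ndarray], y=None) -> "BovwEncoder":
        config = BoVWConfig(
            n_classes=self.n_classes,
            max_iterations=self.max_iterations,
            tol=self.tol,
            seed=self.random_state,
        )
        self.codebook_ = fit_codebook(_pool(X), config)
        self.n_features_out_ = self.codebook_.n_clusters
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "codebook_")
        return encode_dataset(X, self.codebook_, normalize=self.normalize)
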