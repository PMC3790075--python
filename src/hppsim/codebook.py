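"""Acoustic prototype inventories and frame quantization.

Each feature class (static MFCC, delta, delta-delta) gets its own codebook of
prototype vectors learned by seeded k-means; defaults are 150 / 150 / 100
prototypes. A frame is then represented by the labels of its nearest prototype
in each class, so an utterance becomes three parallel label sequences.

The k-means loop is written out (k-means++ seeding via scikit-learn, Lloyd
updates) so that the per-iteration distortion trace is available and empty
clusters can be repaired while keeping the prototype count exact: an empty
cluster's centroid is replaced by the training frame currently worst explained
by its assigned prototype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .core import DataError, ParameterError
from .frontend import FRAME_HOP_MS, FeatureTriple

DEFAULT_SIZES = (150, 150, 100)
MAX_ITER = 50
REL_TOL = 1e-4


@dataclass
class LabelStream:
    """Three parallel 1-based prototype-label sequences for one utterance."""

    labels_static: np.ndarray
    labels_delta: np.ndarray
    labels_deltadelta: np.ndarray
    codebook_sizes: tuple[int, int, int]
    frame_hop_ms: int = FRAME_HOP_MS

    def __post_init__(self) -> None:
        seqs = self.streams()
        if len({s.shape for s in seqs}) != 1:
            raise ParameterError("label sequences must share length")
        for s, k in zip(seqs, self.codebook_sizes):
            if s.size and (s.min() < 1 or s.max() > k):
                raise ParameterError(f"labels out of range [1, {k}]")

    def streams(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.labels_static, self.labels_delta, self.labels_deltadelta

    @property
    def n_frames(self) -> int:
        return self.labels_static.size

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_hop_ms / 1000.0


@dataclass
class CodebookSet:
    """Trained prototype inventories for the three feature classes."""

    prototypes_static: np.ndarray
    prototypes_delta: np.ndarray
    prototypes_deltadelta: np.ndarray
    train_seed: int
    distortion_traces: tuple[list[float], list[float], list[float]] = field(
        default_factory=lambda: ([], [], [])
    )

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (
            self.prototypes_static.shape[0],
            self.prototypes_delta.shape[0],
            self.prototypes_deltadelta.shape[0],
        )

    def books(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.prototypes_static, self.prototypes_delta, self.prototypes_deltadelta


def _sq_dists(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (N, K)."""
    # ||x||^2 - 2 x.c + ||c||^2; clip tiny negatives from cancellation
    d = (
        np.sum(x * x, axis=1)[:, None]
        - 2.0 * x @ centers.T
        + np.sum(centers * centers, axis=1)[None, :]
    )
    return np.maximum(d, 0.0)


def _lloyd(
    x: np.ndarray, k: int, seed: int, max_iter: int, tol: float
) -> tuple[np.ndarray, list[float]]:
    if x.shape[0] < k:
        raise DataError(f"need >= {k} frames to train a {k}-prototype codebook")
    centers, _ = kmeans_plusplus(x, n_clusters=k, random_state=seed)
    centers = centers.copy()
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        d = _sq_dists(x, centers)
        assign = np.argmin(d, axis=1)
        mind = d[np.arange(x.shape[0]), assign]
        distortion = float(np.mean(mind))
        trace.append(distortion)
        if prev - distortion <= tol * max(distortion, 1e-300):
            break
        prev = distortion
        # Lloyd update with exact-count empty-cluster repair
        taken: set[int] = set()
        for j in range(k):
            members = assign == j
            if np.any(members):
                centers[j] = x[members].mean(axis=0)
            else:
                order = np.argsort(mind)[::-1]
                pick = next(int(i) for i in order if int(i) not in taken)
                taken.add(pick)
                centers[j] = x[pick]
    return centers, trace


def train_codebooks(
    features: Sequence[FeatureTriple],
    sizes: tuple[int, int, int] = DEFAULT_SIZES,
    seed: int = 0,
    max_iter: int = MAX_ITER,
    tol: float = REL_TOL,
) -> CodebookSet:
    """Learn the three prototype inventories from pooled training frames.

    Codebooks are trained independently per feature class with seeded k-means
    (Euclidean distortion). Training is reproducible under ``seed``.

    Raises
    ------
    DataError
        If the pooled frame count is below the largest requested codebook.
    """
    if not features:
        raise DataError("no training features")
    if any(s <= 0 for s in sizes):
        raise ParameterError("codebook sizes must be positive")
    pooled = [
        np.concatenate([f.blocks()[c] for f in features], axis=1).T for c in range(3)
    ]
    books: list[np.ndarray] = []
    traces: list[list[float]] = []
    for c, (x, k) in enumerate(zip(pooled, sizes)):
        centers, trace = _lloyd(x, k, seed=seed + c, max_iter=max_iter, tol=tol)
        books.append(centers)
        traces.append(trace)
    return CodebookSet(
        prototypes_static=books[0],
        prototypes_delta=books[1],
        prototypes_deltadelta=books[2],
        train_seed=seed,
        distortion_traces=(traces[0], traces[1], traces[2]),
    )


def quantize(f: FeatureTriple, cb: CodebookSet) -> LabelStream:
    """Replace every frame by the label of its nearest prototype per class.

    Ties are broken toward the lowest prototype index; labels are 1-based.
    """
    labels = []
    for block, book in zip(f.blocks(), cb.books()):
        if block.shape[0] != book.shape[1]:
            raise ParameterError(
                f"feature dim {block.shape[0]} != codebook dim {book.shape[1]}"
            )
        d = _sq_dists(block.T, book)
        labels.append(np.argmin(d, axis=1).astype(np.int64) + 1)
    return LabelStream(
        labels_static=labels[0],
        labels_delta=labels[1],
        labels_deltadelta=labels[2],
        codebook_sizes=cb.sizes,
    )


def save_codebooks(cb: CodebookSet, path) -> None:
    np.savez(
        path,
        static=cb.prototypes_static,
        delta=cb.prototypes_delta,
        deltadelta=cb.prototypes_deltadelta,
        seed=cb.train_seed,
    )


def load_codebooks(path) -> CodebookSet:
    with np.load(path) as z:
        return CodebookSet(
            prototypes_static=z["static"],
            prototypes_delta=z["delta"],
            prototypes_deltadelta=z["deltadelta"],
            train_seed=int(z["seed"]),
        )
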