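"""Histogram of Acoustic Co-occurrences (HAC) encoding.

A label stream of any length is condensed into a fixed-dimension count vector:
for each feature class and each time lag (20 and 50 ms, i.e. 2 and 5 frames at
the 10 ms hop), the ordered pairs ``(label_t, label_{t+L})`` are counted over
all valid t. Pairs are ordered — the lag is directional — so the histogram
keeps some of the temporal structure of the utterance. Under the default
codebook sizes (150, 150, 100) and two lags the vector has
``2 * (150^2 + 150^2 + 100^2) = 110 000`` entries, almost all zero, so counts
are stored sparsely.

Block layout: classes outermost, lags innermost —
``[static@20, static@50, delta@20, delta@50, deltadelta@20, deltadelta@50]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .codebook import LabelStream
from .core import ParameterError

DEFAULT_LAGS_MS = (20, 50)


def hac_dimension(sizes: tuple[int, int, int], n_lags: int = 2) -> int:
    """Dimension of a HAC vector: ``n_lags * (K1^2 + K2^2 + K3^2)``."""
    if any(k <= 0 for k in sizes):
        raise ParameterError("codebook sizes must be positive")
    if n_lags < 1:
        raise ParameterError("need at least one lag")
    return n_lags * sum(k * k for k in sizes)


@dataclass
class HACVector:
    """Sparse non-negative co-occurrence counts for one utterance."""

    counts: sp.csc_matrix  # shape (dimension, 1)
    codebook_sizes: tuple[int, int, int]
    lags_ms: tuple[int, ...] = DEFAULT_LAGS_MS

    @property
    def dimension(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense()).ravel()


def encode_hac(ls: LabelStream, lags_ms: tuple[int, ...] = DEFAULT_LAGS_MS) -> HACVector:
    """Count ordered within-class label pairs at each lag.

    For class c and lag L (in frames), the pair ``(label_t, label_{t+L})`` is
    counted for ``t = 1..T-L``; a stream shorter than a lag contributes zero to
    that block, so the output dimension never depends on the stream length.

    Raises
    ------
    ParameterError
        If a lag is not a multiple of the frame hop.
    """
    hop = ls.frame_hop_ms
    lag_frames = []
    for lag in lags_ms:
        if lag % hop != 0 or lag <= 0:
            raise ParameterError(f"lag {lag} ms not divisible by hop {hop} ms")
        lag_frames.append(lag // hop)

    sizes = ls.codebook_sizes
    dim = hac_dimension(sizes, len(lags_ms))
    idx_parts: list[np.ndarray] = []
    cnt_parts: list[np.ndarray] = []
    offset = 0
    for labels, k in zip(ls.streams(), sizes):
        lab0 = labels - 1  # to 0-based cells
        for lf in lag_frames:
            if labels.size > lf:
                cells = lab0[:-lf] * k + lab0[lf:]
                counts = np.bincount(cells, minlength=k * k)
                nz = np.nonzero(counts)[0]
                idx_parts.append(nz + offset)
                cnt_parts.append(counts[nz])
            offset += k * k
    if idx_parts:
        rows = np.concatenate(idx_parts)
        data = np.concatenate(cnt_parts).astype(np.float64)
    else:
        rows = np.empty(0, dtype=int)
        data = np.empty(0, dtype=np.float64)
    counts = sp.csc_matrix(
        (data, (rows, np.zeros_like(rows))), shape=(dim, 1)
    )
    return HACVector(counts=counts, codebook_sizes=sizes, lags_ms=tuple(lags_ms))


def cosine_similarity(a: HACVector, b: HACVector) -> float:
    """Cosine of the angle between two HAC vectors (0 if either is empty)."""
    if a.dimension != b.dimension:
        raise ParameterError("dimension mismatch")
    num = float((a.counts.T @ b.counts).toarray().squeeze())
    den = float(sp.linalg.norm(a.counts) * sp.linalg.norm(b.counts))
    return num / den if den > 0 else 0.0


def save_hac_csv(v: HACVector, path) -> None:
    """Persist one sparse vector as (index, count) CSV rows."""
    coo = v.counts.tocoo()
    np.savetxt(
        path,
        np.column_stack([coo.row, coo.data]),
        delimiter=",",
        header="index,count",
        comments="",
        fmt=["%d", "%.10g"],
    )
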