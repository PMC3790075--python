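"""Matching by non-negative decomposition with a fixed dictionary.

A test utterance (a HAC vector ``v``) is approximated as a non-negative
weighted sum of all memory columns, ``v ~ W h``, by minimizing the generalized
Kullback-Leibler divergence

    D(v || Wh) = sum_d [ v_d log(v_d / (Wh)_d) - v_d + (Wh)_d ]

over the weights ``h`` only: the dictionary ``W`` is the memory and is never
updated (no learning phase). The classic multiplicative update

    h <- h * (W^T (v / (Wh))) / (W^T 1)

decreases the divergence monotonically and preserves non-negativity. The
weight of a memory entry measures how much that episode contributes to
explaining the input.

Numerical choices: weights start uniform at ``1/M`` (deterministic — the
update is linear in ``v`` on the first step, so decomposition is exactly
1-homogeneous in the input scale); dictionary columns are normalized to unit
sum by default so weights are comparable across entries of different utterance
lengths; iteration stops when the relative divergence decrease falls below
``tol`` (default 1e-6) or at ``max_iter`` (default 500); divisions are floored
at 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import DataError, ParameterError
from .hac import HACVector
from .memory import MemoryBank

EPS = 1e-12
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


@dataclass
class WeightVector:
    """Result of one decomposition: weights plus the convergence record."""

    weights: np.ndarray
    divergence_trace: np.ndarray
    converged: bool
    n_iter: int


def kl_divergence(v, approx) -> float:
    """Generalized KL divergence ``D(v || approx)``.

    Zero entries of ``v`` contribute ``approx_d``; zero entries of ``approx``
    where ``v_d > 0`` are floored at 1e-12, giving a large finite value rather
    than infinity.

    Raises
    ------
    ParameterError
        On negative entries or mismatched dimensions.
    """
    v = np.asarray(v, dtype=np.float64).ravel()
    approx = np.asarray(approx, dtype=np.float64).ravel()
    if v.shape != approx.shape:
        raise ParameterError("dimension mismatch")
    if np.any(v < 0) or np.any(approx < 0):
        raise ParameterError("negative entries")
    pos = v > 0
    a = np.maximum(approx[pos], EPS)
    return float(
        np.sum(v[pos] * np.log(v[pos] / a)) - v[pos].sum() + approx.sum()
    )


def decompose(
    v: HACVector | np.ndarray,
    bank: MemoryBank,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    normalize_columns: bool = True,
) -> WeightVector:
    """Decompose ``v`` over the memory columns by multiplicative KL updates.

    Parameters
    ----------
    v : HACVector or array
        Non-negative input with the bank's dimension and positive total count.
    bank : MemoryBank
        Fixed dictionary; one weight is produced per entry (noise included).
    tol : float
        Relative divergence-decrease stopping threshold.
    seed : int, optional
        Unused by the deterministic uniform initialization; accepted for
        interface stability with randomized-restart variants.
    normalize_columns : bool
        Scale each dictionary column to unit sum before decomposition so that
        weights are comparable across entries of different lengths.

    Raises
    ------
    DataError
        If ``v`` is all-zero.
    ParameterError
        On dimension mismatch.
    """
    dense = v.dense() if isinstance(v, HACVector) else np.asarray(v, dtype=np.float64)
    if dense.shape[0] != bank.dimension:
        raise ParameterError(
            f"input dimension {dense.shape[0]} != memory dimension {bank.dimension}"
        )
    if np.any(dense < 0):
        raise ParameterError("negative entries in input")
    if dense.sum() <= 0:
        raise DataError("cannot decompose an all-zero vector")

    w = bank.dictionary.tocsc().astype(np.float64)
    col_sums = np.asarray(w.sum(axis=0)).ravel()
    if normalize_columns:
        w = w @ sp.diags(1.0 / np.maximum(col_sums, EPS))
        wt_ones = np.ones(bank.size)
    else:
        wt_ones = col_sums
    w = w.tocsr()
    wt = w.T.tocsr()

    m = bank.size
    h = np.full(m, 1.0 / m)
    trace: list[float] = []
    converged = False
    n_iter = 0
    prev = np.inf
    for n_iter in range(1, max_iter + 1):
        wh = w @ h
        h = h * (wt @ (dense / np.maximum(wh, EPS))) / np.maximum(wt_ones, EPS)
        d = kl_divergence(dense, w @ h)
        trace.append(d)
        if np.isfinite(prev) and prev - d <= tol * max(abs(prev), EPS):
            converged = True
            break
        prev = d
    return WeightVector(
        weights=h,
        divergence_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
    )
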