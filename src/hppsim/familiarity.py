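"""Familiarity scores: from decomposition weights to recognition measures.

Two definitions of recognition are compared throughout. *Single-episode
activation* treats every familiarization token as an independent episode: the
score is the largest weight among the familiarization entries. *Cluster
activation* treats all tokens as one cluster of experiences: the score is the
sum of their weights. Both are expressed as a percentage of the total weight
mass over all memory entries (noise included), so they are invariant to a
positive rescaling of the weight vector, and the cluster score can never fall
below the single-episode score.

A score refers to one whole test sentence and becomes available only at the
sentence's end (decomposition operates on the complete utterance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, StateError
from .memory import MemoryBank
from .nmf import WeightVector

CONDITION_FAMILIAR = "familiar"
CONDITION_NOVEL = "novel"


@dataclass(frozen=True)
class ScoreRecord:
    """Familiarity scores of one test sentence under one familiarization set."""

    sentence_id: str
    word_id: str
    condition: str
    single_score_pct: float
    cluster_score_pct: float
    duration_s: float = float("nan")


def _fam_weights(w: WeightVector | np.ndarray, bank: MemoryBank):
    weights = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    fam = bank.familiarization_indices
    if fam.size == 0:
        raise StateError("memory bank has no familiarization entries")
    total = float(weights.sum())
    if total <= 0:
        raise DataError("weight vector sums to zero")
    return weights, fam, total


def single_episode_score(w: WeightVector | np.ndarray, bank: MemoryBank) -> float:
    """Percent of total weight on the single best-matching familiarization token."""
    weights, fam, total = _fam_weights(w, bank)
    return 100.0 * float(weights[fam].max()) / total


def cluster_score(w: WeightVector | np.ndarray, bank: MemoryBank) -> float:
    """Percent of total weight summed over all familiarization tokens."""
    weights, fam, total = _fam_weights(w, bank)
    return 100.0 * float(weights[fam].sum()) / total
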