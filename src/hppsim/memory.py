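"""The episodic memory bank.

The modeled infant's memory is an ordered collection of HAC vectors of three
kinds: *background* utterances standing in for speech experience before the
experiment, the *familiarization* word tokens stored during the familiarization
phase, and one *noise* recording. Under the default design — 100 background
utterances, 2 words x 5 tokens, 1 noise entry — the memory holds 111 vectors.

Familiarization is all-or-nothing: tokens are stored with full attention and
without perceptual noise, so the bank after familiarization is a deterministic
function of its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .core import DataError, ParameterError, StateError
from .hac import HACVector

ROLE_BACKGROUND = "background"
ROLE_FAMILIARIZATION = "familiarization"
ROLE_NOISE = "noise"


@dataclass(frozen=True)
class MemoryEntry:
    role: str
    word_id: str | None = None
    token_id: int | None = None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_BACKGROUND, ROLE_FAMILIARIZATION, ROLE_NOISE):
            raise ParameterError(f"unknown role {self.role!r}")
        has_word = self.word_id is not None and self.token_id is not None
        if (self.role == ROLE_FAMILIARIZATION) != has_word:
            raise ParameterError(
                "word_id/token_id present iff role is familiarization"
            )


@dataclass
class MemoryBank:
    """Ordered memory entries plus the dictionary view used for decomposition.

    ``dictionary`` is a ``dimension x M`` sparse non-negative matrix whose
    column j holds the counts of entry j.
    """

    entries: list[MemoryEntry]
    dictionary: sp.csc_matrix
    codebook_sizes: tuple[int, int, int]
    lags_ms: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def dimension(self) -> int:
        return self.dictionary.shape[0]

    @property
    def familiarization_indices(self) -> np.ndarray:
        """Column indices of familiarization entries, in storage order."""
        return np.array(
            [j for j, e in enumerate(self.entries) if e.role == ROLE_FAMILIARIZATION],
            dtype=int,
        )

    @property
    def is_familiarized(self) -> bool:
        return self.familiarization_indices.size > 0


def _check_vectors(vectors: Sequence[HACVector]) -> None:
    dims = {v.dimension for v in vectors}
    if len(dims) > 1:
        raise ParameterError(f"mixed HAC dimensions: {sorted(dims)}")
    for i, v in enumerate(vectors):
        if v.total <= 0:
            raise DataError(f"memory column {i} has zero total count")


def build_memory(background: Sequence[HACVector], noise: HACVector) -> MemoryBank:
    """Assemble the pre-experiment memory: background entries plus one noise entry.

    An empty background list is allowed (degenerate single-entry memory) but
    triggers a warning.
    """
    if not background:
        warnings.warn("building a memory with no background entries", stacklevel=2)
    vectors = list(background) + [noise]
    _check_vectors(vectors)
    entries = [MemoryEntry(ROLE_BACKGROUND) for _ in background]
    entries.append(MemoryEntry(ROLE_NOISE))
    dictionary = sp.hstack([v.counts for v in vectors], format="csc")
    return MemoryBank(
        entries=entries,
        dictionary=dictionary,
        codebook_sizes=noise.codebook_sizes,
        lags_ms=noise.lags_ms,
    )


def familiarize(
    bank: MemoryBank, tokens: Mapping[str, Sequence[HACVector]]
) -> MemoryBank:
    """Append the familiarization word tokens to a memory bank.

    ``tokens`` maps word id -> its isolated-token HAC vectors (default design:
    2 words x 5 tokens, growing the default 101-entry memory to 111). Returns a
    new bank; the input bank is not modified.

    Raises
    ------
    StateError
        If the bank already holds familiarization entries.
    """
    if bank.is_familiarized:
        raise StateError("memory bank is already familiarized")
    new_entries = list(bank.entries)
    cols: list[sp.csc_matrix] = [bank.dictionary]
    fam_vectors: list[HACVector] = []
    for word_id, word_tokens in tokens.items():
        for token_id, v in enumerate(word_tokens):
            if v.dimension != bank.dimension:
                raise ParameterError(
                    f"token dimension {v.dimension} != memory dimension {bank.dimension}"
                )
            fam_vectors.append(v)
            new_entries.append(
                MemoryEntry(ROLE_FAMILIARIZATION, word_id=word_id, token_id=token_id)
            )
    _check_vectors(fam_vectors)
    cols.extend(v.counts for v in fam_vectors)
    dictionary = sp.hstack(cols, format="csc")
    return MemoryBank(
        entries=new_entries,
        dictionary=dictionary,
        codebook_sizes=bank.codebook_sizes,
        lags_ms=bank.lags_ms,
    )
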