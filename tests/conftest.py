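import numpy as np
import pytest

from hppsim import (
    LabelStream,
    build_memory,
    encode_hac,
    familiarize,
    generate_symbolic_stream,
    make_speaker_profile,
)

SMALL_SIZES = (5, 5, 4)


@pytest.fixture
def speaker():
    return make_speaker_profile("S1", 1.0, 0.0, 3)


@pytest.fixture
def stream_factory(speaker):
    """Random small label streams with tiny codebooks."""

    def make(n_frames=30, seed=0, word=None, sizes=SMALL_SIZES):
        return generate_symbolic_stream(word, speaker, n_frames, sizes, seed)

    return make


@pytest.fixture
def hac_factory(stream_factory):
    def make(n_frames=30, seed=0):
        return encode_hac(stream_factory(n_frames=n_frames, seed=seed))

    return make


@pytest.fixture
def small_bank(hac_factory):
    """Memory of 5 background + 1 noise + 2 words x 5 tokens (M = 16)."""
    background = [hac_factory(seed=s) for s in range(5)]
    noise = hac_factory(n_frames=20, seed=90)
    bank = build_memory(background, noise)
    tokens = {
        "wa": [hac_factory(n_frames=12, seed=100 + s) for s in range(5)],
        "wb": [hac_factory(n_frames=12, seed=200 + s) for s in range(5)],
    }
    return familiarize(bank, tokens)
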