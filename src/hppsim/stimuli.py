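"""Synthetic stimulus generation.

The original corpus behind published headturn-preference experiments (four
adult speakers; four monosyllabic target words; isolated word tokens; short
carrier sentences; background utterances) is not publicly deposited, so this
module generates stand-in stimuli with the same design: per speaker, 5
isolated tokens of each of 4 target words, 24 carrier sentences per word (mean
duration between roughly 2.7 and 3.0 s, each containing exactly one embedded
target), 100 background utterances containing no target, and one noise
recording.

Words are pseudo-syllables built from additive harmonic (voiced) and filtered
noise (unvoiced) segments with fixed formant-like spectral envelopes — no
intelligible speech is needed, because the downstream model consumes only
spectral envelopes. A speaker is modeled as a time-scale factor (speakers
differ measurably in speech rate), a spectral warp, and a private seed;
MFCC-style features carry no pitch, so pitch is not modeled.

A symbolic fast path (:func:`generate_symbolic_stream`) emits prototype-label
streams directly, bypassing audio synthesis and quantization, for tests and
reduced-scale experiments. Speaker effects there are a seeded label-alphabet
permutation (driven by the spectral warp), a time-stretch of the embedded word
pattern (speech rate), and optional label noise.

Every output is a pure function of its arguments including seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .codebook import LabelStream
from .core import ParameterError, Waveform

DEFAULT_SAMPLE_RATE = 16000


def _stable_hash(token: str) -> int:
    return zlib.crc32(token.encode("utf-8"))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SpeakerProfile:
    """A synthetic speaker: rate scaling, spectral warp, private seed."""

    speaker_id: str
    rate_factor: float
    spectral_shift: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.5 <= self.rate_factor <= 2.0:
            raise ParameterError("rate_factor must lie in [0.5, 2.0]")


def make_speaker_profile(
    speaker_id: str, rate_factor: float, spectral_shift: float, seed: int
) -> SpeakerProfile:
    """Deterministic speaker profile; equal arguments give equal profiles."""
    return SpeakerProfile(speaker_id, float(rate_factor), float(spectral_shift), int(seed))


@dataclass(frozen=True)
class Segment:
    """One pseudo-syllable segment: duration plus a spectral-envelope recipe."""

    duration_ms: float
    formants_hz: tuple[float, ...]
    voiced: bool = True
    gain: float = 1.0


@dataclass(frozen=True)
class WordSpec:
    """A target word as a sequence of segment descriptors."""

    word_id: str
    template: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.template:
            raise ParameterError("word template must have at least one segment")
        if not 300.0 <= self.duration_ms <= 700.0:
            raise ParameterError(
                f"template duration {self.duration_ms:g} ms outside [300, 700]"
            )

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.template)


def default_words() -> tuple[WordSpec, WordSpec, WordSpec, WordSpec]:
    """Four monosyllable-like targets (stop-like burst + vowel-like nucleus),
    pairwise distinct in their segment descriptors."""
    return (
        WordSpec("frog", (Segment(90, (1400.0, 2600.0), voiced=False, gain=0.5),
                          Segment(360, (600.0, 1100.0)))),
        WordSpec("doll", (Segment(70, (900.0, 2100.0), voiced=False, gain=0.5),
                          Segment(420, (700.0, 1250.0)))),
        WordSpec("duck", (Segment(80, (1600.0, 3000.0), voiced=False, gain=0.5),
                          Segment(300, (650.0, 1500.0)))),
        WordSpec("ball", (Segment(60, (800.0, 1800.0), voiced=False, gain=0.5),
                          Segment(440, (450.0, 950.0)))),
    )


# filler syllable inventory shared across speakers (carrier sentences were
# identical for all speakers; only the realization varies)
FILLER_SEGMENTS: tuple[tuple[Segment, ...], ...] = (
    (Segment(180, (350.0, 2000.0)),),
    (Segment(160, (500.0, 1600.0)),),
    (Segment(200, (750.0, 1300.0)),),
    (Segment(150, (300.0, 2400.0)),),
    (Segment(60, (2000.0, 3600.0), voiced=False, gain=0.4), Segment(140, (550.0, 1750.0))),
    (Segment(220, (420.0, 2200.0)),),
    (Segment(170, (850.0, 1450.0)),),
    (Segment(50, (1200.0, 2800.0), voiced=False, gain=0.4), Segment(180, (480.0, 1900.0))),
    (Segment(190, (620.0, 2500.0)),),
    (Segment(140, (380.0, 1150.0)),),
)

_PAUSE_MS = 30.0


@dataclass
class StimulusSet:
    """Everything one synthetic speaker contributes to an experiment."""

    isolated_tokens: dict[str, list[Waveform]]
    sentences: dict[str, list[tuple[Waveform, dict]]]
    background: list[Waveform]
    noise: Waveform
    speaker: SpeakerProfile


# ---------------------------------------------------------------------------
# audio synthesis


def _synth_segment(
    seg: Segment,
    duration_s: float,
    speaker: SpeakerProfile,
    sample_rate_hz: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = max(int(round(duration_s * sample_rate_hz)), 8)
    warp = 1.0 + speaker.spectral_shift
    nyq_cap = 0.45 * sample_rate_hz
    freqs = [min(max(f * warp, 60.0), nyq_cap) for f in seg.formants_hz]
    t = np.arange(n) / sample_rate_hz
    if seg.voiced:
        out = np.zeros(n)
        for i, f in enumerate(freqs):
            phase = rng.uniform(0, 2 * np.pi)
            out += np.sin(2 * np.pi * f * t + phase) / (i + 1.0)
    else:
        noise = rng.standard_normal(n)
        lo = max(0.6 * min(freqs), 50.0)
        hi = min(1.4 * max(freqs), nyq_cap)
        sos = scipy.signal.butter(2, [lo, hi], btype="band", fs=sample_rate_hz, output="sos")
        out = scipy.signal.sosfilt(sos, noise)
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out / peak
    return out * seg.gain * np.hanning(n)


def _synth_segments(
    segments: Sequence[Segment],
    scale: float,
    speaker: SpeakerProfile,
    sample_rate_hz: int,
    rng: np.random.Generator,
) -> np.ndarray:
    parts = [
        _synth_segment(s, s.duration_ms / 1000.0 * scale, speaker, sample_rate_hz, rng)
        for s in segments
    ]
    return np.concatenate(parts)


def _normalize(samples: np.ndarray, peak: float = 0.9) -> np.ndarray:
    m = np.max(np.abs(samples))
    return samples * (peak / m) if m > 0 else samples


def synthesize_word_token(
    word: WordSpec,
    speaker: SpeakerProfile,
    jitter_seed: int,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
    jitter_pct: float = 0.1,
) -> Waveform:
    """One isolated realization of a target word.

    Duration is ``template duration x rate_factor x (1 + jitter)`` with jitter
    drawn uniformly from ``+-jitter_pct`` under ``jitter_seed``; spectral
    content is the template warped by the speaker's spectral shift.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([speaker.seed, int(jitter_seed), _stable_hash(word.word_id)])
    )
    jitter = rng.uniform(-jitter_pct, jitter_pct) if jitter_pct > 0 else 0.0
    scale = speaker.rate_factor * (1.0 + jitter)
    samples = _synth_segments(word.template, scale, speaker, sample_rate_hz, rng)
    return Waveform(_normalize(samples), sample_rate_hz)


def _filler_audio(
    target_s: float,
    speaker: SpeakerProfile,
    sample_rate_hz: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Filler syllables (plus short pauses) totaling about ``target_s`` seconds."""
    parts: list[np.ndarray] = []
    total = 0.0
    pause = int(round(_PAUSE_MS / 1000.0 * sample_rate_hz))
    while total < target_s:
        syll = FILLER_SEGMENTS[rng.integers(0, len(FILLER_SEGMENTS))]
        audio = _synth_segments(syll, speaker.rate_factor, speaker, sample_rate_hz, rng)
        parts.append(audio)
        parts.append(np.zeros(pause))
        total += audio.size / sample_rate_hz + _PAUSE_MS / 1000.0
    return parts


def synthesize_sentence(
    word: WordSpec,
    speaker: SpeakerProfile,
    target_duration_s: float,
    seed: int,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
) -> tuple[Waveform, dict]:
    """A carrier sentence with exactly one embedded target-word realization.

    The target duration is interpreted at nominal rate and scaled by the
    speaker's rate factor; total duration lands within about 10% of the scaled
    target. The annotation records the word onset/offset in seconds.
    """
    word_dur_s = word.duration_ms / 1000.0 * speaker.rate_factor
    effective_target = target_duration_s * speaker.rate_factor
    if effective_target < word_dur_s:
        raise ParameterError(
            f"target {target_duration_s:g} s too short for word "
            f"({word.duration_ms / 1000.0:g} s at rate {speaker.rate_factor:g})"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([speaker.seed, int(seed), _stable_hash(word.word_id), 2])
    )
    word_audio = _synth_segments(
        word.template, speaker.rate_factor, speaker, sample_rate_hz, rng
    )
    filler = _filler_audio(
        max(effective_target - word_dur_s, 0.0), speaker, sample_rate_hz, rng
    )
    slot = int(rng.integers(0, len(filler) + 1))
    onset_samples = sum(p.size for p in filler[:slot])
    parts = filler[:slot] + [word_audio] + filler[slot:]
    samples = _normalize(np.concatenate(parts))
    annotation = {
        "word_id": word.word_id,
        "word_onset_s": onset_samples / sample_rate_hz,
        "word_offset_s": (onset_samples + word_audio.size) / sample_rate_hz,
    }
    return Waveform(samples, sample_rate_hz), annotation


def synthesize_background(
    speaker: SpeakerProfile,
    target_duration_s: float,
    seed: int,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
) -> Waveform:
    """A filler-only utterance containing no target-word template."""
    rng = np.random.default_rng(np.random.SeedSequence([speaker.seed, int(seed), 3]))
    parts = _filler_audio(
        target_duration_s * speaker.rate_factor, speaker, sample_rate_hz, rng
    )
    return Waveform(_normalize(np.concatenate(parts)), sample_rate_hz)


# ---------------------------------------------------------------------------
# experiment-design generation


@dataclass(frozen=True)
class StimulusDesign:
    """Counts and distributions of the stimulus inventory per speaker."""

    n_words: int = 4
    n_tokens: int = 5
    n_sentences_per_word: int = 24
    n_background: int = 100
    sentence_duration_mean_s: float = 2.85
    sentence_duration_sd_s: float = 0.35
    sentence_duration_range_s: tuple[float, float] = (2.0, 4.0)
    background_duration_mean_s: float = 2.5
    background_duration_sd_s: float = 0.5
    noise_duration_s: float = 2.0
    token_jitter_pct: float = 0.1
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if min(self.n_words, self.n_tokens, self.n_sentences_per_word, self.n_background) <= 0:
            raise ParameterError("design counts must be positive")


def generate_stimulus_set(
    words: Sequence[WordSpec],
    speaker: SpeakerProfile,
    design: StimulusDesign | None = None,
    seed: int = 0,
) -> StimulusSet:
    """The full stimulus inventory of one speaker, bit-reproducible under ``seed``."""
    design = design or StimulusDesign()
    if len(words) != design.n_words:
        raise ParameterError(
            f"design expects {design.n_words} words, got {len(words)}"
        )
    sr = design.sample_rate_hz
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), speaker.seed, 11]))

    tokens: dict[str, list[Waveform]] = {}
    for word in words:
        tokens[word.word_id] = [
            synthesize_word_token(
                word, speaker, jitter_seed=int(rng.integers(0, 2**31)),
                sample_rate_hz=sr, jitter_pct=design.token_jitter_pct,
            )
            for _ in range(design.n_tokens)
        ]

    lo, hi = design.sentence_duration_range_s
    sentences: dict[str, list[tuple[Waveform, dict]]] = {}
    for word in words:
        items = []
        for _ in range(design.n_sentences_per_word):
            target = float(
                np.clip(
                    rng.normal(design.sentence_duration_mean_s, design.sentence_duration_sd_s),
                    lo, hi,
                )
            )
            items.append(
                synthesize_sentence(
                    word, speaker, target, seed=int(rng.integers(0, 2**31)),
                    sample_rate_hz=sr,
                )
            )
        sentences[word.word_id] = items

    background = [
        synthesize_background(
            speaker,
            float(
                np.clip(
                    rng.normal(design.background_duration_mean_s, design.background_duration_sd_s),
                    1.0, 5.0,
                )
            ),
            seed=int(rng.integers(0, 2**31)),
            sample_rate_hz=sr,
        )
        for _ in range(design.n_background)
    ]

    noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), speaker.seed, 13]))
    noise = Waveform(
        np.clip(noise_rng.normal(0.0, 0.005, int(design.noise_duration_s * sr)), -1, 1),
        sr,
    )
    return StimulusSet(
        isolated_tokens=tokens,
        sentences=sentences,
        background=background,
        noise=noise,
        speaker=speaker,
    )


def write_stimulus_set(sset: StimulusSet, out_dir) -> "pd.DataFrame":
    """Write PCM-16 WAV files plus a manifest CSV; returns the manifest frame."""
    import pandas as pd
    from pathlib import Path
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []

    def _write(name: str, w: Waveform, role: str, word_id="", onset=np.nan, offset=np.nan):
        path = out / name
        wavfile.write(path, w.sample_rate_hz, (w.samples * 32767).astype(np.int16))
        rows.append(
            dict(file=name, role=role, word_id=word_id,
                 speaker_id=sset.speaker.speaker_id, duration_s=w.duration_s,
                 word_onset_s=onset, word_offset_s=offset)
        )

    for wid, toks in sset.isolated_tokens.items():
        for i, w in enumerate(toks):
            _write(f"token_{wid}_{i:02d}.wav", w, "familiarization", wid)
    for wid, sents in sset.sentences.items():
        for i, (w, ann) in enumerate(sents):
            _write(f"sentence_{wid}_{i:02d}.wav", w, "test", wid,
                   ann["word_onset_s"], ann["word_offset_s"])
    for i, w in enumerate(sset.background):
        _write(f"background_{i:03d}.wav", w, "background")
    _write("noise.wav", sset.noise, "noise")

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# symbolic fast path


def _word_pattern(
    word: WordSpec, codebook_sizes: tuple[int, int, int], rate_factor: float
) -> list[np.ndarray]:
    """The word's deterministic label subsequence per class, stretched by rate."""
    base_len = max(4, int(round(word.duration_ms / 10.0)))
    out = []
    for c, k in enumerate(codebook_sizes):
        rng_w = np.random.default_rng(
            np.random.SeedSequence([_stable_hash(word.word_id), 101 + c])
        )
        base = rng_w.integers(1, k + 1, base_len)
        stretched_len = max(2, int(round(base_len * rate_factor)))
        idx = np.minimum((np.arange(stretched_len) * base_len) // stretched_len, base_len - 1)
        out.append(base[idx])
    return out


def _speaker_permutations(
    speaker: SpeakerProfile, codebook_sizes: tuple[int, int, int]
) -> list[np.ndarray]:
    """Label-alphabet permutation per class; strength scales with |spectral_shift|."""
    perms = []
    for c, k in enumerate(codebook_sizes):
        perm = np.arange(1, k + 1)
        m = min(k, int(round(abs(speaker.spectral_shift) * k)))
        if m >= 2:
            rng_s = np.random.default_rng(
                np.random.SeedSequence([speaker.seed, 211 + c])
            )
            chosen = rng_s.choice(k, size=m, replace=False)
            perm[chosen] = perm[np.roll(chosen, 1)]
        perms.append(perm)
    return perms


def generate_symbolic_stream(
    word: WordSpec | None,
    speaker: SpeakerProfile,
    n_frames: int,
    codebook_sizes: tuple[int, int, int],
    seed: int,
    label_noise: float = 0.0,
) -> LabelStream:
    """Label streams produced directly, without audio synthesis or quantization.

    Filler frames carry uniform random labels; if ``word`` is given, its
    deterministic label pattern (stretched by the speaker's rate factor) is
    embedded contiguously at a seeded position. The speaker's spectral shift
    acts as a label-alphabet permutation; ``label_noise`` flips each frame's
    label to a random one with the given probability.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), speaker.seed, 31]))
    streams = [rng.integers(1, k + 1, n_frames) for k in codebook_sizes]

    if word is not None:
        patterns = _word_pattern(word, codebook_sizes, speaker.rate_factor)
        length = patterns[0].size
        if length > n_frames:
            raise ParameterError(
                f"word pattern ({length} frames) longer than stream ({n_frames})"
            )
        pos = int(rng.integers(0, n_frames - length + 1))
        for s, p in zip(streams, patterns):
            s[pos : pos + length] = p

    perms = _speaker_permutations(speaker, codebook_sizes)
    streams = [perm[s - 1] for s, perm in zip(streams, perms)]

    if label_noise > 0.0:
        for s, k in zip(streams, codebook_sizes):
            flip = rng.random(n_frames) < label_noise
            s[flip] = rng.integers(1, k + 1, int(flip.sum()))

    return LabelStream(
        labels_static=streams[0],
        labels_delta=streams[1],
        labels_deltadelta=streams[2],
        codebook_sizes=tuple(codebook_sizes),
    )


def generate_symbolic_set(
    words: Sequence[WordSpec],
    speaker: SpeakerProfile,
    design: StimulusDesign,
    codebook_sizes: tuple[int, int, int],
    seed: int,
    label_noise: float = 0.0,
) -> dict:
    """Symbolic analogue of :func:`generate_stimulus_set`.

    Returns a dict with keys ``tokens`` (word -> list of LabelStreams),
    ``sentences`` (word -> list of (sentence_id, LabelStream)), ``background``
    (list of LabelStreams) and ``noise`` (one LabelStream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), speaker.seed, 41]))

    def sub() -> int:
        return int(rng.integers(0, 2**31))

    tokens = {}
    for word in words:
        pat_len = max(2, int(round(word.duration_ms / 10.0 * speaker.rate_factor)))
        tokens[word.word_id] = [
            generate_symbolic_stream(
                word, speaker, pat_len + 8, codebook_sizes, sub(), label_noise
            )
            for _ in range(design.n_tokens)
        ]
    lo, hi = design.sentence_duration_range_s
    sentences = {}
    for word in words:
        items = []
        for i in range(design.n_sentences_per_word):
            target = float(
                np.clip(
                    rng.normal(design.sentence_duration_mean_s, design.sentence_duration_sd_s),
                    lo, hi,
                )
            )
            n_frames = max(10, int(round(target * 100.0 * speaker.rate_factor)))
            items.append(
                (
                    f"{speaker.speaker_id}_{word.word_id}_{i:02d}",
                    generate_symbolic_stream(
                        word, speaker, n_frames, codebook_sizes, sub(), label_noise
                    ),
                )
            )
        sentences[word.word_id] = items
    background = [
        generate_symbolic_stream(
            None, speaker,
            max(10, int(round(
                float(np.clip(
                    rng.normal(design.background_duration_mean_s, design.background_duration_sd_s),
                    1.0, 5.0,
                )) * 100.0 * speaker.rate_factor
            ))),
            codebook_sizes, sub(), label_noise,
        )
        for _ in range(design.n_background)
    ]
    noise = generate_symbolic_stream(
        None, speaker, int(design.noise_duration_s * 100), codebook_sizes, sub(), label_noise
    )
    return dict(tokens=tokens, sentences=sentences, background=background, noise=noise)
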