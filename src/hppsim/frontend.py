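"""Acoustic front end: short-time MFCC analysis with first and second differences.

The continuous waveform is cut into 20 ms windows that overlap by 10 ms, giving
100 analysis frames per second. Each window is reduced to 13 mel-frequency
cepstral coefficients (MFCCs). Because auditory processing is more sensitive to
spectral change than to static spectra, the first difference of adjacent MFCC
vectors (delta) and the difference of adjacent deltas (delta-delta) are appended,
for 39 coefficients per frame in total.

Conventional analysis choices that the frame/coefficient counts do not pin down:
Hamming window, pre-emphasis 0.97, 26 triangular mel filters up to Nyquist, the
cepstrum truncated to coefficients 0-12, and a floor of 1e-10 on filterbank
energies so that silence produces finite features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .core import DataError, ParameterError, TooShortInputError, Waveform

FRAME_LEN_MS = 20
FRAME_HOP_MS = 10
N_CEPSTRA = 13
N_MEL_FILTERS = 26
PREEMPHASIS = 0.97
LOG_FLOOR = 1e-10


@dataclass
class FeatureTriple:
    """Per-frame static / delta / delta-delta cepstra for one utterance.

    Each block is a ``13 x T`` matrix over the same T frames.
    """

    static: np.ndarray
    delta: np.ndarray
    deltadelta: np.ndarray
    frame_hop_ms: int = FRAME_HOP_MS
    frame_len_ms: int = FRAME_LEN_MS

    def __post_init__(self) -> None:
        shapes = {self.static.shape, self.delta.shape, self.deltadelta.shape}
        if len(shapes) != 1:
            raise ParameterError("static/delta/deltadelta must share shape")
        if self.static.shape[0] != N_CEPSTRA:
            raise ParameterError(f"expected {N_CEPSTRA} rows per block")

    @property
    def n_frames(self) -> int:
        return self.static.shape[1]

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.static, self.delta, self.deltadelta


def frame_count(duration_ms: float) -> int:
    """Number of 20 ms windows at a 10 ms hop that fit in ``duration_ms``.

    ``floor((duration_ms - 20) / 10) + 1``; the long-run rate is 100 frames/s.

    Raises
    ------
    TooShortInputError
        If the signal is shorter than a single window.
    """
    if duration_ms < FRAME_LEN_MS:
        raise TooShortInputError(
            f"need at least {FRAME_LEN_MS} ms of signal, got {duration_ms:g} ms"
        )
    return int(math.floor((duration_ms - FRAME_LEN_MS) / FRAME_HOP_MS)) + 1


def _mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(sample_rate_hz: int, n_fft: int, n_filters: int) -> np.ndarray:
    """Triangular filters, equally spaced on the mel scale from 0 Hz to Nyquist."""
    nyquist = sample_rate_hz / 2.0
    mel_points = np.linspace(0.0, _mel(nyquist), n_filters + 2)
    hz_points = np.asarray(_mel_inv(mel_points))
    bins = np.floor((n_fft + 1) * hz_points / sample_rate_hz).astype(int)
    fbank = np.zeros((n_filters, n_fft // 2 + 1))
    for j in range(n_filters):
        left, center, right = bins[j], bins[j + 1], bins[j + 2]
        # degenerate at low resolution: guarantee each filter spans >= 1 bin
        center = max(center, left + 1)
        right = max(right, center + 1)
        for k in range(left, center):
            fbank[j, k] = (k - left) / (center - left)
        for k in range(center, min(right, fbank.shape[1] - 1) + 1):
            if k < fbank.shape[1]:
                fbank[j, k] = (right - k) / (right - center)
    return fbank


def compute_features(w: Waveform) -> FeatureTriple:
    """MFCC / delta / delta-delta analysis of a mono waveform.

    Deltas are backward first differences of the static cepstra with a
    zero-padded first frame; delta-deltas apply the same difference to the
    deltas.

    Raises
    ------
    TooShortInputError
        If the waveform is shorter than one 20 ms window.
    DataError
        If samples are non-finite (already rejected by :class:`Waveform`).
    """
    x = np.asarray(w.samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples")
    n_frames = frame_count(w.duration_ms)  # raises on short input

    win = int(round(w.sample_rate_hz * FRAME_LEN_MS / 1000.0))
    hop = int(round(w.sample_rate_hz * FRAME_HOP_MS / 1000.0))

    # pre-emphasis over the whole signal keeps interior frames shift-covariant
    pre = np.empty_like(x)
    pre[0] = x[0]
    pre[1:] = x[1:] - PREEMPHASIS * x[:-1]

    idx = hop * np.arange(n_frames)[:, None] + np.arange(win)[None, :]
    frames = pre[idx] * np.hamming(win)[None, :]

    spectrum = np.abs(scipy.fft.rfft(frames, n=win, axis=1)) ** 2
    fbank = _mel_filterbank(w.sample_rate_hz, win, N_MEL_FILTERS)
    energies = np.log(np.maximum(spectrum @ fbank.T, LOG_FLOOR))
    cepstra = scipy.fft.dct(energies, type=2, norm="ortho", axis=1)[:, :N_CEPSTRA]

    static = cepstra.T  # 13 x T
    delta = np.zeros_like(static)
    delta[:, 1:] = static[:, 1:] - static[:, :-1]
    deltadelta = np.zeros_like(static)
    deltadelta[:, 1:] = delta[:, 1:] - delta[:, :-1]
    return FeatureTriple(static=static, delta=delta, deltadelta=deltadelta)


def features_to_csv(f: FeatureTriple, path) -> None:
    """Dump the 39 x T coefficient matrix of one utterance as CSV."""
    mat = np.vstack(f.blocks())
    np.savetxt(path, mat, delimiter=",")
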