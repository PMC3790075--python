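"""Shared primitives: error taxonomy and the mono waveform container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class DataError(ValueError):
    """Input data are structurally valid but unusable (e.g. empty, non-finite)."""


class TooShortInputError(DataError):
    """A signal is shorter than one analysis window."""


class StateError(RuntimeError):
    """An operation was called on an object in the wrong state."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal.

    Attributes
    ----------
    samples : np.ndarray
        1-D float array, all values finite, peak magnitude <= 1.
    sample_rate_hz : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ParameterError("waveform must be mono (1-D)")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        if samples.size and not np.all(np.isfinite(samples)):
            raise DataError("waveform contains non-finite samples")
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise DataError("waveform peak amplitude exceeds 1")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate_hz

    def __eq__(self, other: object) -> bool:  # dataclass eq fails on arrays
        if not isinstance(other, Waveform):
            return NotImplemented
        return (
            self.sample_rate_hz == other.sample_rate_hz
            and self.samples.shape == other.samples.shape
            and bool(np.all(self.samples == other.samples))
        )
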