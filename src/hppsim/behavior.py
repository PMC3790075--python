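"""Attention dynamics and simulated listening times.

The per-sentence familiarity scores of a test passage are turned into a pulse
train: a pulse at the passage onset with amplitude ``theta + rho`` (the
modeled infant starts the trial attending to the flashing lamp) and one pulse
at the end of each sentence whose amplitude is that sentence's familiarity
score expressed as a proportion (percent / 100). An exponential decay with
rate ``alpha`` — the attention span; larger alpha, shorter span — converts the
pulses into a continuous attention function.

Two readings of "attention is renewed at each pulse" are supported:

* ``superpose`` (default): the impulse train is convolved with the
  exponential, so contributions of past pulses add up,
  ``A(t) = sum_{t_i <= t} a_i exp(-alpha (t - t_i))``.
* ``reset``: each pulse replaces the attention level,
  ``A(t) = a_k exp(-alpha (t - t_k))`` for the latest pulse ``k``.

The simulated experimenter applies a threshold ``theta``: time with attention
at or above theta counts as listening; if attention stays below theta for more
than 2 consecutive seconds the trial is terminated at the start of that
below-threshold interval and later pulses are ignored. A pulse arriving while
the head is briefly turned away (before the 2 s elapse) can rescue the trial —
in a real experiment the audio keeps playing during short look-aways.

Listening times are computed analytically: attention decays monotonically
between pulses, so each inter-pulse segment has at most one downward threshold
crossing, solvable in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ParameterError

DEFAULT_RHO = 0.4
DEFAULT_AWAY_LIMIT_S = 2.0
MODE_SUPERPOSE = "superpose"
MODE_RESET = "reset"


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the attention/decision model.

    alpha : exponential decay rate per second (> 0); the attention span.
    theta : experimenter threshold (> 0) on the attention function.
    rho   : onset offset; attention at trial start is theta + rho.
    away_limit_s : maximal tolerated below-threshold run (the 2-second rule).
    mode  : 'superpose' or 'reset' (see module docstring).
    """

    alpha: float
    theta: float
    rho: float = DEFAULT_RHO
    away_limit_s: float = DEFAULT_AWAY_LIMIT_S
    mode: str = MODE_SUPERPOSE

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")
        if self.theta <= 0:
            raise ParameterError("theta must be positive")
        if self.rho <= 0:
            raise ParameterError("rho must be positive")
        if self.away_limit_s <= 0:
            raise ParameterError("away_limit_s must be positive")
        if self.mode not in (MODE_SUPERPOSE, MODE_RESET):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PulseTrain:
    """Score pulses of one test passage.

    ``pulse_times_s[0] = 0`` is the onset pulse with amplitude ``theta + rho``;
    ``pulse_times_s[i]`` for i >= 1 is the cumulative end time of sentence i,
    with amplitude equal to that sentence's familiarity score as a proportion.
    The last pulse coincides with the passage end.
    """

    pulse_times_s: np.ndarray
    amplitudes: np.ndarray
    passage_duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.pulse_times_s, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape or t.ndim != 1 or t.size < 2:
            raise ParameterError("times and amplitudes must be 1-D of equal length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("pulse times must be strictly increasing")
        if np.any(a < 0):
            raise ParameterError("amplitudes must be non-negative")
        object.__setattr__(self, "pulse_times_s", t)
        object.__setattr__(self, "amplitudes", a)


def build_pulse_train(
    scores_pct: Sequence[float],
    durations_s: Sequence[float],
    params: BehaviorParams,
) -> PulseTrain:
    """Pulse train for one passage of N sentences.

    Pulse times are ``(0, d_1, d_1+d_2, ..., sum d_i)``; amplitudes are
    ``(theta + rho, s_1/100, ..., s_N/100)``.
    """
    scores = np.asarray(scores_pct, dtype=float)
    durations = np.asarray(durations_s, dtype=float)
    if scores.size == 0 or durations.size == 0:
        raise ParameterError("need at least one sentence")
    if scores.shape != durations.shape:
        raise ParameterError("scores and durations must have equal length")
    if np.any(durations <= 0):
        raise ParameterError("durations must be positive")
    times = np.concatenate([[0.0], np.cumsum(durations)])
    amplitudes = np.concatenate([[params.theta + params.rho], scores / 100.0])
    return PulseTrain(
        pulse_times_s=times,
        amplitudes=amplitudes,
        passage_duration_s=float(times[-1]),
    )


def attention_at(
    pt: PulseTrain, alpha: float, t, mode: str = MODE_SUPERPOSE
):
    """Attention function value at time(s) ``t`` in ``[0, passage_duration]``.

    Superpose mode sums the decayed contributions of all past pulses; reset
    mode keeps only the latest pulse. Accepts a scalar or an array of times.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0) or np.any(t_arr > pt.passage_duration_s + 1e-12):
        raise ParameterError("t outside [0, passage_duration]")
    times, amps = pt.pulse_times_s, pt.amplitudes
    if mode == MODE_SUPERPOSE:
        dt = t_arr[:, None] - times[None, :]
        contrib = np.where(dt >= 0, amps[None, :] * np.exp(-alpha * np.maximum(dt, 0)), 0.0)
        out = contrib.sum(axis=1)
    elif mode == MODE_RESET:
        k = np.searchsorted(times, t_arr, side="right") - 1
        out = amps[k] * np.exp(-alpha * (t_arr - times[k]))
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return out if np.ndim(t) else float(out[0])


def listening_time(
    pt: PulseTrain, params: BehaviorParams
) -> tuple[float, float | None]:
    """Cumulative above-threshold time of a passage, under the 2-second rule.

    Walks the attention trace segment by segment (a segment spans two adjacent
    pulses; attention decays monotonically inside it, so it crosses ``theta``
    downward at most once, at ``t_k + ln(S_k / theta) / alpha``). Time with
    attention >= theta accumulates as listening. A maximal below-threshold
    interval longer than ``away_limit_s`` terminates the trial at the start of
    that interval; later pulses are ignored. Below-threshold time is never
    counted.

    Returns ``(listening_s, terminated_at_s)`` with ``terminated_at_s = None``
    when the passage runs to completion.
    """
    alpha, theta = params.alpha, params.theta
    limit = params.away_limit_s
    times, amps = pt.pulse_times_s, pt.amplitudes
    n_segments = times.size - 1

    listening = 0.0
    below_start: float | None = None
    carry = 0.0  # superposed attention arriving at the current pulse time
    for k in range(n_segments):
        t0, t1 = times[k], times[k + 1]
        level = carry + amps[k] if params.mode == MODE_SUPERPOSE else amps[k]
        if below_start is not None and level >= theta:
            below_start = None  # pulse rescues the trial (run was <= limit)
        if below_start is None:
            if level >= theta:
                # downward crossing inside this segment, if any
                t_cross = t0 + math.log(level / theta) / alpha if level > 0 else t0
                if t_cross >= t1:
                    listening += t1 - t0
                else:
                    listening += t_cross - t0
                    below_start = t_cross
            else:
                below_start = t0
        if below_start is not None and t1 - below_start > limit:
            # no pulse arrives in time; trial ended when the head turned away
            return listening, float(below_start)
        carry = level * math.exp(-alpha * (t1 - t0))
    return listening, None
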