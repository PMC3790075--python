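import math

import numpy as np
import pytest

from hppsim import (
    BehaviorParams,
    ParameterError,
    attention_at,
    build_pulse_train,
    listening_time,
)


def _params(alpha=0.1, theta=0.4, rho=0.4, mode="superpose"):
    return BehaviorParams(alpha=alpha, theta=theta, rho=rho, mode=mode)


def _random_train(rng, params, n_max=8):
    n = int(rng.integers(1, n_max))
    scores = rng.uniform(0, 80, n)
    durations = rng.uniform(1.0, 4.0, n)
    return build_pulse_train(scores, durations, params)


def grid_listening_time(pt, params, dt=0.001):
    """Independent oracle: evaluate attention on a 1 ms grid and apply the
    threshold and 2-second rule discretely."""
    t = np.arange(0.0, pt.passage_duration_s, dt)
    above = attention_at(pt, params.alpha, t, mode=params.mode) >= params.theta
    listening = 0.0
    below_start = None
    for i, ok in enumerate(above[:-1]):
        now = t[i]
        if ok:
            below_start = None
            listening += dt
        else:
            if below_start is None:
                below_start = now
            if now + dt - below_start > params.away_limit_s:
                return listening, below_start
    return listening, None


class TestPulseTrain:
    def test_onset_amplitude_is_theta_plus_rho(self):
        pt = build_pulse_train([10.0, 20.0], [3.0, 3.0], _params(theta=0.4, rho=0.4))
        assert pt.amplitudes[0] == pytest.approx(0.8)

    def test_times_are_cumulative_sentence_ends(self):
        pt = build_pulse_train([0.0] * 6, [3.0] * 6, _params())
        assert np.allclose(pt.pulse_times_s, [0, 3, 6, 9, 12, 15, 18])
        assert pt.passage_duration_s == pytest.approx(18.0)

    def test_scores_become_proportion_amplitudes(self):
        pt = build_pulse_train([25.0, 50.0], [2.0, 2.0], _params())
        assert np.allclose(pt.amplitudes[1:], [0.25, 0.50])

    def test_empty_sequences_rejected(self):
        with pytest.raises(ParameterError):
            build_pulse_train([], [], _params())


class TestAttention:
    def test_no_decay_at_onset(self):
        pt = build_pulse_train([10.0], [5.0], _params())
        assert attention_at(pt, 0.1, 0.0) == pytest.approx(0.8)

    def test_single_pulse_closed_form(self):
        pt = build_pulse_train([0.0], [5.0], _params())
        assert attention_at(pt, 0.1, 2.0) == pytest.approx(0.8 * math.exp(-0.2))

    def test_small_alpha_limits(self):
        params = _params()
        pt = build_pulse_train([30.0, 40.0], [2.0, 2.0], params)
        t = 3.0  # after the second pulse
        sup = attention_at(pt, 1e-9, t, mode="superpose")
        res = attention_at(pt, 1e-9, t, mode="reset")
        assert sup == pytest.approx(0.8 + 0.3, abs=1e-6)  # cumulative sum
        assert res == pytest.approx(0.3, abs=1e-6)  # last amplitude only

    def test_out_of_range_time_rejected(self):
        pt = build_pulse_train([10.0], [5.0], _params())
        with pytest.raises(ParameterError):
            attention_at(pt, 0.1, 6.0)


class TestListeningTime:
    def test_single_pulse_threshold_crossing_closed_form(self):
        # attention starts at theta+rho and decays; no later pulse rescues
        params = _params(alpha=0.25, theta=0.4, rho=0.4)
        pt = build_pulse_train([0.0], [10.0], params)
        lt, terminated = listening_time(pt, params)
        expected = math.log(0.8 / 0.4) / 0.25  # ln(2)/0.25
        assert lt == pytest.approx(expected, abs=1e-9)
        assert terminated == pytest.approx(expected, abs=1e-9)

    def test_tiny_theta_gives_full_passage_duration(self):
        params = BehaviorParams(alpha=0.2, theta=1e-6, rho=0.4)
        pt = build_pulse_train([5.0, 5.0, 5.0], [3.0, 3.0, 3.0], params)
        lt, terminated = listening_time(pt, params)
        assert lt == pytest.approx(9.0)
        assert terminated is None

    def test_strict_theta_gives_near_zero_listening(self):
        # theta > 1.5 with proportion-scale scores: only the onset interval counts
        params = _params(alpha=0.2, theta=1.6, rho=0.4)
        pt = build_pulse_train([60.0] * 6, [3.0] * 6, params)
        lt, terminated = listening_time(pt, params)
        # only the onset interval (plus a brief superposed rescue) counts
        assert terminated is not None
        assert lt < 1.5 < pt.passage_duration_s

    def test_rescuing_pulse_keeps_trial_alive(self):
        # attention dips below theta for < 2 s before a strong pulse arrives
        params = _params(alpha=1.0, theta=0.4, rho=0.4)
        pt = build_pulse_train([80.0, 0.0], [2.0, 3.0], params)
        # crossing at ln(2) ~ 0.69 s; below for 2 - 0.69 = 1.31 s < 2 s, rescued
        lt, terminated = listening_time(pt, params)
        assert terminated is not None or lt > math.log(2.0)
        first_above = math.log(0.8 / 0.4)
        assert lt > first_above

    def test_termination_at_start_of_long_below_interval(self):
        params = _params(alpha=1.0, theta=0.4, rho=0.4)
        pt = build_pulse_train([0.0, 0.0], [3.0, 3.0], params)
        lt, terminated = listening_time(pt, params)
        assert terminated == pytest.approx(math.log(2.0), abs=1e-9)
        assert lt == pytest.approx(math.log(2.0), abs=1e-9)

    def test_monotone_in_theta_and_alpha(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            params = _params(alpha=0.2, theta=0.5)
            pt = _random_train(rng, params)
            thetas = [0.1, 0.3, 0.5, 0.8, 1.2]
            lts = [
                listening_time(pt, _params(alpha=0.2, theta=th))[0] for th in thetas
            ]
            assert all(a >= b - 1e-9 for a, b in zip(lts, lts[1:]))
            alphas = [0.01, 0.05, 0.1, 0.2, 0.3]
            lts_a = [
                listening_time(pt, _params(alpha=al, theta=0.5))[0] for al in alphas
            ]
            assert all(a >= b - 1e-9 for a, b in zip(lts_a, lts_a[1:]))

    def test_bounds(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            params = _params(
                alpha=float(rng.uniform(0.01, 0.3)),
                theta=float(rng.uniform(0.1, 1.5)),
            )
            pt = _random_train(rng, params)
            lt, _ = listening_time(pt, params)
            assert 0.0 <= lt <= pt.passage_duration_s + 1e-9

    @pytest.mark.parametrize("mode", ["superpose", "reset"])
    def test_agrees_with_millisecond_grid_oracle(self, mode):
        rng = np.random.default_rng(17)
        for _ in range(60):
            params = BehaviorParams(
                alpha=float(rng.uniform(0.05, 0.3)),
                theta=float(rng.uniform(0.1, 1.2)),
                rho=0.4,
                mode=mode,
            )
            pt = _random_train(rng, params)
            analytic, _ = listening_time(pt, params)
            gridded, _ = grid_listening_time(pt, params)
            assert analytic == pytest.approx(gridded, abs=0.02)

    def test_reset_mode_drops_history(self):
        # a zero-score pulse kills attention instantly in reset mode only
        superpose = _params(alpha=0.01, theta=0.4, mode="superpose")
        reset = _params(alpha=0.01, theta=0.4, mode="reset")
        pt_s = build_pulse_train([0.0, 0.0], [1.0, 1.0], superpose)
        lt_superpose, _ = listening_time(pt_s, superpose)
        lt_reset, _ = listening_time(pt_s, reset)
        assert lt_superpose > lt_reset
        assert lt_reset == pytest.approx(1.0)  # above theta only until pulse 1


def test_invalid_parameters_rejected():
    for kwargs in (
        dict(alpha=0.0, theta=0.4),
        dict(alpha=0.1, theta=-0.1),
        dict(alpha=0.1, theta=0.4, mode="bogus"),
    ):
        with pytest.raises(ParameterError):
            BehaviorParams(rho=0.4, **kwargs)
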