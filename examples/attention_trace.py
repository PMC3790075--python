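"""Attention decay and listening time for one test passage.

Builds a pulse train from six sentence familiarity scores and shows how the
listening time depends on the attention-span parameter alpha: the attention
function starts at theta + rho = 0.8, is renewed at each sentence end, and
decays exponentially in between; once it stays below theta for more than two
consecutive seconds the trial ends.
"""

from hppsim import BehaviorParams, build_pulse_train, listening_time

scores_pct = [22.0, 8.0, 15.0, 3.0, 18.0, 11.0]  # per-sentence familiarity (%)
durations_s = [2.8, 3.1, 2.6, 2.9, 3.0, 2.7]

print(f"passage duration: {sum(durations_s):.1f} s")
for alpha in (0.05, 0.15, 0.25):
    params = BehaviorParams(alpha=alpha, theta=0.4, rho=0.4)
    train = build_pulse_train(scores_pct, durations_s, params)
    lt, terminated = listening_time(train, params)
    status = f"aborted at {terminated:.2f} s" if terminated else "ran to the end"
    print(f"alpha={alpha:.2f}: listening time {lt:5.2f} s ({status})")

# Longer attention spans (smaller alpha) keep attention above the
# experimenter threshold longer, so listening time shrinks as alpha grows.
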