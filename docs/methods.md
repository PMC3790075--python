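# Methods

## Scope and model structure

`hppsim` simulates a two-phase headturn-preference experiment as a strict
feed-forward pipeline. The modeled infant owns an episodic memory of
acoustic experiences; familiarization stores word tokens in that memory with
full attention and no perceptual noise; the test phase decomposes each test
sentence over the whole memory and converts the resulting familiarity scores
into headturn behavior through an attention function that a simulated
experimenter thresholds. Nothing in the chain segments words from running
speech: words and sentences alike are represented as bags of acoustic
co-occurrence events, which is the point of the architecture — a listening
preference can emerge without any segmentation skill.

## Acoustic front end

Frames are 20 ms with a 10 ms hop (100 frames/s; `floor((d−20)/10)+1` frames
for a `d` ms signal). Counts and timing are the model's fixed
configuration; the remaining analysis choices are the conventional ones:
pre-emphasis 0.97, Hamming window, 26 triangular mel filters up to Nyquist,
log filterbank energies floored at 1e−10 (so silence stays finite), DCT-II
(orthonormal), cepstra 0–12 retained. Δ features are backward first
differences with a zero-padded first frame, ΔΔ the same applied to Δ —
deliberately the simplest compliant scheme; regression-window deltas would
be a stronger smoother than the model description warrants. Whether the
0th cepstral coefficient should be replaced by log-energy is unknowable from
the configuration counts alone; c0 is retained.

## Prototypes and label streams

Codebooks of 150/150/100 prototypes (static/Δ/ΔΔ) are trained independently
per class with seeded k-means (k-means++ initialization, Lloyd updates,
at most 50 iterations, relative distortion tolerance 1e−4). The Lloyd loop
is implemented in-package so the per-iteration distortion trace is an
inspectable invariant (it must be non-increasing) and so empty clusters can
be repaired without changing the prototype count: an empty centroid is
replaced by the currently worst-explained training frame. Training data are
the experiment speaker's background utterances — the only pre-experiment
material the model owns. Quantization assigns each frame the nearest
prototype per class (Euclidean; ties to the lowest index). Labels are
1-based.

## HAC encoding

For each class and each lag L ∈ {20, 50} ms (2 and 5 frames), ordered pairs
`(label_t, label_{t+L})` are counted over all valid t. Ordered (directional)
pairs are used because the lag is directional and order carries temporal
structure; cross-class pairs are not counted. Counts are raw integers — no
per-utterance length normalization is applied by default, because the KL
objective operates naturally on counts and the decomposition stage can
normalize dictionary columns instead (see below). The vector dimension,
2·(150²+150²+100²) = 110 000, is independent of utterance length; storage is
sparse.

## Memory

Default memory: 100 background utterances + 1 noise entry + 2 words × 5
familiarization tokens = 111 columns. The noise entry is an ordinary column:
it participates in decomposition and in the weight-mass normalization of the
scores. The background size is configurable (the preference effect is not
expected to depend critically on it; the weights of familiarization tokens
shrink as background grows, but familiar/novel *differences* are preserved).
Familiarization is guarded against being applied twice.

## KL-NMF decomposition

A test HAC vector `v` is approximated as `Wh` with `W` the fixed memory
dictionary and `h ≥ 0`, minimizing the generalized KL divergence
`Σ_d v_d log(v_d/(Wh)_d) − v_d + (Wh)_d`. Multiplicative updates
`h ← h ⊙ Wᵀ(v ⊘ Wh) ⊘ Wᵀ1` are monotone and preserve non-negativity; the
dictionary is never updated. Design choices the model description leaves
open, fixed as follows and exposed as arguments:

* **Initialization** uniform `h = 1/M`, deterministic. The first update is
  linear in `v`, so the whole trajectory is exactly 1-homogeneous in the
  input scale (`decompose(c·v) = c·decompose(v)`), a property the tests
  assert.
* **Column normalization** to unit sum, on by default, making weights
  comparable across memory entries of different utterance lengths.
* **Stopping**: relative divergence decrease below 1e−6 or 500 iterations;
  divisions floored at 1e−12 (a zero model entry against a positive count
  yields a large finite divergence rather than ∞).

On problems small enough to search exhaustively (dimension ≤ 6, M ≤ 3) the
final divergence matches a dense scan of the weight simplex to 1e−3; with
unit-sum columns the optimal total mass equals `Σv`, which reduces that scan
to simplex directions.

## Familiarity scores

Single-episode activation = `100 · max_{j∈fam} h_j / Σ_j h_j`; cluster
activation = `100 · Σ_{j∈fam} h_j / Σ_j h_j`. Both use the full M-entry mass
(noise included) as the denominator, are invariant to positive rescaling of
`h`, and satisfy cluster ≥ single. Scores exist per whole sentence and only
at its end; there is no within-sentence (continuous-time) recognition.

## Attention and the experimenter

A passage of N sentences yields pulses at times `(0, d₁, d₁+d₂, …, Σdᵢ)`
with amplitudes `(θ+ρ, s₁/100, …, s_N/100)`: scores enter as proportions,
putting typical amplitudes on the same order-unity scale as the θ grid. The
onset amplitude θ + ρ (ρ = 0.4 by default) models initial interest in the
flashing lamp; with θ = 0.4 the trial starts at attention 0.8.

The printed decay formula (a pulse train convolved with `e^{−αt}`) and the
prose reading ("attention is renewed at each pulse") genuinely differ, so
both are first-class modes: `superpose` (default; contributions add) and
`reset` (each pulse replaces the level). α is the attention span — larger α,
faster decay, shorter span — and is held constant within an experiment.

Listening time accumulates the time the attention function is **at or
above** θ (equality counts; it is measure-zero in continuous time but must
be fixed for discrete evaluators), up to the moment the function stays below
θ for more than 2 consecutive seconds, at which point the trial terminates
at the *start* of that below-threshold interval. A pulse arriving during a
shorter dip takes effect and can rescue the trial — in a real experiment the
audio keeps playing during brief look-aways. Evaluation is event-driven and
analytic: between pulses attention is a single decaying exponential, so the
unique downward crossing is `t_k + ln(S_k/θ)/α`. A 1 ms grid evaluator
serves as an independent oracle in the tests (agreement within 20 ms on
random pulse trains; the analytic path itself is exact to floating point,
verified against the closed form `ln((θ+ρ)/θ)/α` for single-pulse trains to
1 ms over 1000 random draws).

Monotonicity consequences asserted as properties: listening time is
non-increasing in θ and (superpose mode) non-increasing in α; θ → 0 yields
the full passage duration; θ > 1.5 with proportion-scale scores yields
near-zero listening times.

## Experiments and statistics

The default design: 4 target words partitioned into two familiarization sets
of 2; 24 test sentences per word (96 per speaker), each scored under both
memories — once familiar, once novel; 30 six-sentence passages per word
sampled with replacement; every passage evaluated in both conditions, so
each comparison pools 120 familiar and 120 novel listening times over
identical durations (the duration-bias control). Sentence scores are
compared with the Mann–Whitney U test (exact p by enumeration for combined
n ≤ 12 without ties, otherwise normal approximation with tie and continuity
corrections — delegated to scipy, cross-checked in the tests against
exhaustive permutation enumeration). Passage listening times are compared
with Welch's t test (the safer default where only "two-sample t test" is
specified; a pooled-variance variant is available). The {α, θ} sweep runs
α = 0.01…0.30 and θ = 0.10…1.50 in steps of 0.01 (4230 cells), records
means, SDs, t, p and the preference sign per cell, and applies no
multiple-comparison correction — an explicit modeling choice: contiguous
significance trajectories in the {α, θ} plane are themselves the evidence
of a systematic underlying effect.

## Synthetic stimuli

The original four-speaker infant-directed corpus is proprietary, so the
generator emulates its design rather than its content. Audio words are
pseudo-syllables (a noise-burst segment plus a voiced vowel-like segment
with fixed formant pairs, 300–700 ms templates); carrier sentences embed
exactly one word realization among filler syllables drawn from an inventory
shared across speakers (the sentences were identical across speakers in the
emulated design; ~2.7–3.0 s mean duration at nominal rate, SD 0.35 s);
background utterances are filler-only; the noise entry is low-amplitude
white noise. Speakers are modeled as a rate factor in [0.5, 2.0] (speech
rate is the documented measurable speaker difference), a spectral warp, and
a seed; pitch is not modeled because MFCC envelopes do not represent it, and
no speaker normalization is applied anywhere. Sample rate defaults to
16 kHz; token durations jitter by ±10%.

The symbolic fast path emits the post-quantization label streams directly:
filler frames are uniform random labels, each word has a deterministic label
pattern whose length scales with the speaker's rate factor, the spectral
warp becomes a partial label-alphabet permutation, and optional label noise
flips labels at a given rate. This path exists because the downstream model
is agnostic to how label streams arose; it makes reduced-scale end-to-end
experiments roughly two orders of magnitude cheaper than the audio route.

**What the generator does not emulate:** real phonetic variability,
coarticulation between the embedded word and its context, prosody,
infant-directed register, and recording-channel effects. Passing end-to-end
tests therefore demonstrate that the *machinery* recovers a designed
familiarity signal under the stated noise model — not that the model
reproduces any particular empirical listening-time values, which depend on
the unavailable corpus.

## Problem sizes used in the shipped checks

End-to-end checks run the symbolic route at reduced scale — 12 sentences per
word, 50 background utterances, 10 passages per word, codebooks (20, 20, 10),
and a coarsened grid (α step 0.04, θ step 0.10) — across 20 master seeds;
the audio route runs once at miniature scale (8 kHz, 12-background, (12, 12, 8)
codebooks). These sizes are the package's own choice of a desk-scale
experiment; the full default configuration is available through the same
functions.

## Known limitations

* The decomposition is convex in `h` but multiplicative updates converge
  sublinearly near sparse optima; the 1e−6 relative tolerance trades
  exactness for speed and the tests bound the gap against brute force.
* Attention during familiarization is not modeled (storage is perfect), so
  infant-specific effects enter only through α.
* The superpose/reset ambiguity is resolved by configuration, not by data;
  results that depend on the mode should be reported for both.
* Grid cells are tested independently; the deliberate absence of a
  multiple-comparison correction means isolated significant cells should not
  be over-interpreted.
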