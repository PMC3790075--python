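# hppsim

A computational simulation of the **Headturn Preference Procedure** (HPP),
the behavioral paradigm used to study speech processing in pre-verbal
infants. In an HPP experiment an infant is first familiarized with isolated
spoken words and then hears six-sentence test passages that do or do not
contain those words; the time the head stays turned toward the loudspeaker
("listening time") is the behavioral measure. `hppsim` models the whole
chain from the speech waveform to the listening-time statistics, so that the
assumptions linking overt behavior to internal processing — and the influence
of the infant's attention span and of the experimenter's headturn criterion —
can be studied in simulation.

## The model

The processing chain is strictly feed-forward:

1. **Acoustic front end** — 20 ms windows with a 10 ms hop (100 frames/s),
   13 MFCCs per frame plus first (Δ) and second (ΔΔ) differences: 39
   coefficients per frame.
2. **Prototype quantization** — three seeded k-means codebooks (150 static,
   150 Δ, 100 ΔΔ prototypes) trained on the speaker's background utterances;
   each frame becomes a triple of prototype labels.
3. **HAC encoding** — an utterance of any length becomes a fixed-dimension
   **Histogram of Acoustic Co-occurrences**: counts of ordered within-class
   label pairs at lags of 20 and 50 ms, a sparse vector with
   2·(150² + 150² + 100²) = 110 000 entries.
4. **Episodic memory** — 100 background HAC vectors + 1 noise vector + 10
   familiarization tokens (2 words × 5 tokens) = 111 entries.
5. **Matching** — each test sentence `v` is approximated as a non-negative
   weighted sum of all memory columns, `v ≈ Wh`, by minimizing the
   generalized Kullback–Leibler divergence with multiplicative updates; the
   dictionary `W` is fixed (no learning phase).
6. **Familiarity scores** — *single-episode activation*: the maximum weight
   among the familiarization entries; *cluster activation*: their sum; both
   as a percentage of the total weight mass.
7. **Behavior generation** — scores become pulses at sentence ends; an
   exponential decay with rate α (the attention span) yields a continuous
   attention function with onset level θ + ρ (ρ = 0.4).
8. **Experimenter model** — listening time is the cumulative time the
   attention function is at or above the threshold θ, up to the moment it
   stays below θ for more than 2 consecutive seconds. Sweeping
   α ∈ [0.01, 0.30] and θ ∈ [0.10, 1.50] and testing the familiar–novel
   listening-time difference per cell (two-sample t test, p < 0.05) yields a
   significance grid (a Hinton-plot).

Sentence-level score differences are assessed with the Mann–Whitney U test;
passages are compared with Welch's t test on 120 familiar vs 120 novel
passages, each passage used once in either condition so durations cancel.

Because the corpus used in published HPP modeling work is not publicly
available, the package ships a seeded synthetic-stimulus generator with the
same design (4 target words × 5 isolated tokens, 24 carrier sentences per
word, 100 background utterances, 1 noise recording per speaker; speakers
differ in speech rate and spectral warp), plus a symbolic fast path that
emits prototype-label streams directly.

## Worked example

```python
from hppsim import Design, make_speaker_profile, mann_whitney_u
from hppsim.experiment import run_symbolic_experiment
from hppsim.stimuli import StimulusDesign

design = Design(words=("frog", "doll", "duck", "ball"),
                n_sentences_per_word=12, n_passages_per_word=10, seed=5)
speaker = make_speaker_profile("S1", 1.0, 0.0, 3)
scores, grids = run_symbolic_experiment(
    design, speaker, speaker,
    stimulus_design=StimulusDesign(n_tokens=5, n_sentences_per_word=12,
                                   n_background=50),
    codebook_sizes=(20, 20, 10), seed=5)

fam = scores.loc[scores.condition == "familiar", "cluster_score_pct"]
nov = scores.loc[scores.condition == "novel", "cluster_score_pct"]
print(fam.mean(), nov.mean(), mann_whitney_u(fam, nov))
```

prints (same-speaker condition, cluster activation):

```
17.79 2.30 (2304.0, 3.23e-17)
```

i.e. sentences containing a familiarized word assign 17.8% of the
decomposition weight mass to the familiarization tokens versus 2.3% for
novel words — a highly significant internal familiarity effect — and the
accompanying `grids["cluster"]` table marks the {α, θ} region where that
effect surfaces as significantly longer listening times.

The `examples/` directory holds one short narrative script per capability
(stimulus generation, sentence scoring, attention traces, the significance
sweep). A thin CLI wraps the same functions:

```bash
hppsim generate-stimuli --out stimuli/ --seed 1
hppsim run --config config.yaml --out results/ --seed 1
hppsim sweep --scores results/scores.csv --out results/ --seed 1
```

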