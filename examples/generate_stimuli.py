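"""Synthesize a small stimulus inventory for one speaker and inspect it.

Generates isolated word tokens, carrier sentences with word annotations, and
background utterances; writes WAV files plus a manifest CSV under
scratch/stimuli (kept small here: 2 tokens, 3 sentences per word, 5
background utterances; the experiment default is 5 / 24 / 100).
"""

from hppsim import default_words, generate_stimulus_set, make_speaker_profile
from hppsim.stimuli import StimulusDesign, write_stimulus_set

speaker = make_speaker_profile("F1", rate_factor=0.93, spectral_shift=0.05, seed=7)
design = StimulusDesign(n_tokens=2, n_sentences_per_word=3, n_background=5)
stimuli = generate_stimulus_set(default_words(), speaker, design, seed=1)

word = "frog"
token = stimuli.isolated_tokens[word][0]
sentence, annotation = stimuli.sentences[word][0]
print(f"speaker {speaker.speaker_id}: rate x{speaker.rate_factor}")
print(f"isolated '{word}' token: {token.duration_s:.3f} s")
print(
    f"carrier sentence: {sentence.duration_s:.2f} s, word at "
    f"{annotation['word_onset_s']:.2f}-{annotation['word_offset_s']:.2f} s"
)
print(f"background utterances: {len(stimuli.background)}")

manifest = write_stimulus_set(stimuli, "scratch/stimuli")
print(f"wrote {len(manifest)} WAV files + manifest to scratch/stimuli/")
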