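"""Full simulated headturn-preference experiments.

An experiment pairs a familiarization speaker with a test speaker. The
familiarization speaker contributes the background experience, the noise
recording, and the isolated word tokens; the test speaker contributes the
carrier sentences. Two memories are built, one familiarized with each half of
the four-word partition, and every test sentence is decomposed against both,
yielding a familiar-condition and a novel-condition score per sentence (each
sentence is used once as familiar and once as novel). Sentence-level score
differences are assessed with the Mann-Whitney U test.

Test passages of six sentences of one word are assembled by sampling with
replacement; each passage is evaluated under both memories, so the familiar
and novel listening-time samples contain the same passages (identical
durations — the duration-bias control). For every {alpha, theta} cell of the
sweep, listening times of the familiar and novel passage sets are compared
with a two-sample t test (Welch by default; no multiple-comparison
correction, significance level 0.05), yielding the significance grid behind a
Hinton-style plot.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import codebook as cb
from . import frontend
from .behavior import BehaviorParams, build_pulse_train, listening_time
from .core import DataError, ParameterError, StateError
from .familiarity import (
    CONDITION_FAMILIAR,
    CONDITION_NOVEL,
    ScoreRecord,
    cluster_score,
    single_episode_score,
)
from .hac import HACVector, encode_hac
from .memory import MemoryBank, build_memory, familiarize
from .nmf import decompose
from .stimuli import StimulusSet

P_SIGNIFICANT = 0.05
DEFAULT_ALPHAS = np.round(np.arange(0.01, 0.301, 0.01), 10)
DEFAULT_THETAS = np.round(np.arange(0.10, 1.501, 0.01), 10)
SIGN_FAMILIAR = "familiar"
SIGN_NOVEL = "novel"
SIGN_NONE = "none"


@dataclass(frozen=True)
class Design:
    """The four-word, two-familiarization-set experimental design."""

    words: tuple[str, str, str, str]
    familiarization_sets: tuple[tuple[str, str], tuple[str, str]] = None  # type: ignore[assignment]
    n_tokens: int = 5
    n_sentences_per_word: int = 24
    n_passages_per_word: int = 30
    passage_len: int = 6
    speaker_pair: tuple[str, str] = ("S1", "S1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.familiarization_sets is None:
            object.__setattr__(
                self,
                "familiarization_sets",
                (tuple(self.words[:2]), tuple(self.words[2:])),
            )
        flat = [w for s in self.familiarization_sets for w in s]
        if sorted(flat) != sorted(self.words) or len(self.words) != 4:
            raise ParameterError("familiarization sets must partition the 4 words")
        if min(self.n_tokens, self.n_sentences_per_word, self.n_passages_per_word,
               self.passage_len) <= 0:
            raise ParameterError("design counts must be positive")

    def fam_set_of(self, word_id: str) -> int:
        for i, s in enumerate(self.familiarization_sets):
            if word_id in s:
                return i
        raise ParameterError(f"unknown word {word_id!r}")


# ---------------------------------------------------------------------------
# sentence scoring


def score_label_streams(
    test_sentences: Mapping[str, Sequence[tuple[str, cb.LabelStream]]],
    fam_tokens: Mapping[str, Sequence[cb.LabelStream]],
    background: Sequence[cb.LabelStream],
    noise: cb.LabelStream,
    design: Design,
    lags_ms: tuple[int, ...] = (20, 50),
    nmf_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Score every test sentence under both familiarization sets.

    Returns one row per (sentence, familiarization set): sentence_id, word_id,
    fam_set, condition, single/cluster scores in percent, duration_s.
    """
    nmf_kwargs = nmf_kwargs or {}
    bg_hacs = [encode_hac(s, lags_ms) for s in background]
    noise_hac = encode_hac(noise, lags_ms)
    base = build_memory(bg_hacs, noise_hac)
    banks: list[MemoryBank] = []
    for fam_set in design.familiarization_sets:
        tokens = {
            wid: [encode_hac(s, lags_ms) for s in fam_tokens[wid]] for wid in fam_set
        }
        banks.append(familiarize(base, tokens))

    rows = []
    for wid, sentences in test_sentences.items():
        for sid, stream in sentences:
            v = encode_hac(stream, lags_ms)
            duration = stream.duration_s
            for set_idx, bank in enumerate(banks):
                w = decompose(v, bank, **nmf_kwargs)
                condition = (
                    CONDITION_FAMILIAR
                    if design.fam_set_of(wid) == set_idx
                    else CONDITION_NOVEL
                )
                rows.append(
                    dict(
                        sentence_id=sid,
                        word_id=wid,
                        fam_set=set_idx,
                        condition=condition,
                        single_score_pct=single_episode_score(w, bank),
                        cluster_score_pct=cluster_score(w, bank),
                        duration_s=duration,
                    )
                )
    return pd.DataFrame(rows)


def score_all_sentences(
    design: Design,
    fam_stimuli: StimulusSet,
    test_stimuli: StimulusSet,
    codebooks: cb.CodebookSet | None = None,
    codebook_sizes: tuple[int, int, int] = cb.DEFAULT_SIZES,
    codebook_seed: int = 0,
    lags_ms: tuple[int, ...] = (20, 50),
    nmf_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Audio-route sentence scoring.

    Features are extracted for all material; prototype codebooks are trained
    on the familiarization speaker's background utterances (the only
    pre-experiment material the modeled infant owns) unless ``codebooks`` is
    supplied; everything is quantized, HAC-encoded and scored under both
    familiarization memories. Under the default design this yields 96 test
    sentences and 192 score records.
    """
    if not fam_stimuli.isolated_tokens or not test_stimuli.sentences:
        raise StateError("stimulus sets are incomplete")
    bg_feats = [frontend.compute_features(w) for w in fam_stimuli.background]
    if codebooks is None:
        if not bg_feats:
            raise DataError("no background utterances to train codebooks on")
        codebooks = cb.train_codebooks(bg_feats, sizes=codebook_sizes, seed=codebook_seed)

    def q(w) -> cb.LabelStream:
        return cb.quantize(frontend.compute_features(w), codebooks)

    background = [cb.quantize(f, codebooks) for f in bg_feats]
    noise = q(fam_stimuli.noise)
    fam_tokens = {
        wid: [q(w) for w in toks] for wid, toks in fam_stimuli.isolated_tokens.items()
    }
    test_sentences = {
        wid: [
            (f"{test_stimuli.speaker.speaker_id}_{wid}_{i:02d}", q(w))
            for i, (w, _ann) in enumerate(sents)
        ]
        for wid, sents in test_stimuli.sentences.items()
    }
    return score_label_streams(
        test_sentences, fam_tokens, background, noise, design,
        lags_ms=lags_ms, nmf_kwargs=nmf_kwargs,
    )


# ---------------------------------------------------------------------------
# statistics


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with a two-sided p value.

    The p value is exact when the combined sample size is at most 12 and there
    are no ties, otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic with Welch-Satterthwaite df, two-sided p.

    Raises
    ------
    ParameterError
        If a sample has fewer than two values or both variances are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ParameterError("both samples are degenerate (zero variance)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical samples
        res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pooled_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Equal-variance (pooled) two-sample t test; same contract as welch_t."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ParameterError("both samples are degenerate (zero variance)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# passages and the {alpha, theta} sweep


def assemble_passages(
    sentence_ids: Mapping[str, Sequence[str]],
    design: Design,
    seed: int | None = None,
) -> dict[str, list[list[str]]]:
    """Per word, ``n_passages_per_word`` passages of ``passage_len`` sentence
    ids sampled with replacement under the design seed."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    out: dict[str, list[list[str]]] = {}
    for wid in design.words:
        ids = list(sentence_ids.get(wid, []))
        if not ids:
            raise ParameterError(f"no sentences for word {wid!r}")
        out[wid] = [
            [ids[j] for j in rng.integers(0, len(ids), design.passage_len)]
            for _ in range(design.n_passages_per_word)
        ]
    return out


def _passage_arrays(
    passages: Mapping[str, Sequence[Sequence[str]]],
    scores: pd.DataFrame,
    score_mode: str,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per passage: (durations, familiar-condition scores, novel-condition scores)."""
    col = f"{score_mode}_score_pct"
    if col not in scores.columns:
        raise ParameterError(f"unknown score mode {score_mode!r}")
    lookup: dict[tuple[str, str], float] = {}
    durations: dict[str, float] = {}
    for row in scores.itertuples():
        lookup[(row.sentence_id, row.condition)] = getattr(row, col)
        durations[row.sentence_id] = row.duration_s
    out = []
    for wid, plist in passages.items():
        for sids in plist:
            try:
                d = np.array([durations[s] for s in sids])
                fam = np.array([lookup[(s, CONDITION_FAMILIAR)] for s in sids])
                nov = np.array([lookup[(s, CONDITION_NOVEL)] for s in sids])
            except KeyError as e:
                raise StateError(f"scores missing for sentence {e.args[0]}") from None
            out.append((d, fam, nov))
    return out


def run_grid(
    passages: Mapping[str, Sequence[Sequence[str]]],
    scores: pd.DataFrame,
    score_mode: str = "cluster",
    alphas: np.ndarray = DEFAULT_ALPHAS,
    thetas: np.ndarray = DEFAULT_THETAS,
    rho: float = 0.4,
    away_limit_s: float = 2.0,
    mode: str = "superpose",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Listening-time significance over the {alpha, theta} grid.

    Every passage is evaluated in both conditions at each cell; the familiar
    and novel listening-time samples are compared with a two-sample t test
    (Welch unless ``equal_var``). The preference sign is 'familiar' when
    p < 0.05 and the familiar mean is larger, 'novel' when reversed, 'none'
    otherwise (including degenerate equal samples).
    """
    alphas = np.asarray(alphas, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if alphas.size == 0 or thetas.size == 0:
        raise ParameterError("grids must be non-empty")
    arrays = _passage_arrays(passages, scores, score_mode)
    ttest = pooled_t if equal_var else welch_t

    records = []
    for alpha in alphas:
        for theta in thetas:
            params = BehaviorParams(
                alpha=float(alpha), theta=float(theta), rho=rho,
                away_limit_s=away_limit_s, mode=mode,
            )
            lt_fam = np.empty(len(arrays))
            lt_nov = np.empty(len(arrays))
            for i, (d, fam, nov) in enumerate(arrays):
                lt_fam[i] = listening_time(build_pulse_train(fam, d, params), params)[0]
                lt_nov[i] = listening_time(build_pulse_train(nov, d, params), params)[0]
            diff = lt_fam.mean() - lt_nov.mean()
            if np.var(lt_fam, ddof=1) == 0 and np.var(lt_nov, ddof=1) == 0:
                t_stat, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
            else:
                t_stat, p = ttest(lt_fam, lt_nov)
            if p < P_SIGNIFICANT and diff > 0:
                sign = SIGN_FAMILIAR
            elif p < P_SIGNIFICANT and diff < 0:
                sign = SIGN_NOVEL
            else:
                sign = SIGN_NONE
            records.append(
                dict(
                    alpha=float(alpha), theta=float(theta),
                    mean_fam=lt_fam.mean(), sd_fam=lt_fam.std(ddof=1),
                    mean_nov=lt_nov.mean(), sd_nov=lt_nov.std(ddof=1),
                    t=t_stat, p=p, sign=sign,
                )
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# export


def score_summary(scores: pd.DataFrame, speaker_pair: tuple[str, str]) -> pd.DataFrame:
    """Mean/SD per condition and score mode plus the Mann-Whitney comparison."""
    rows = []
    for mode in ("single", "cluster"):
        col = f"{mode}_score_pct"
        fam = scores.loc[scores.condition == CONDITION_FAMILIAR, col].to_numpy()
        nov = scores.loc[scores.condition == CONDITION_NOVEL, col].to_numpy()
        u, p = mann_whitney_u(fam, nov)
        for condition, sample in ((CONDITION_FAMILIAR, fam), (CONDITION_NOVEL, nov)):
            rows.append(
                dict(
                    familiarization_speaker=speaker_pair[0],
                    test_speaker=speaker_pair[1],
                    mode=mode, condition=condition,
                    mean_pct=sample.mean(), sd_pct=sample.std(ddof=1),
                    U=u, p=p,
                )
            )
    return pd.DataFrame(rows)


def export_results(
    grids: Mapping[str, pd.DataFrame],
    scores: pd.DataFrame,
    out_dir,
    speaker_pair: tuple[str, str] = ("S1", "S1"),
    hinton: bool = False,
) -> list[Path]:
    """Write grid and score-summary CSVs (and optional Hinton plots).

    ``grids`` maps score mode -> grid frame. Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for mode, grid in grids.items():
        path = out / f"grid_{mode}.csv"
        grid.to_csv(path, index=False)
        written.append(path)
        if hinton:
            written.append(hinton_plot(grid, out / f"hinton_{mode}.png"))
    path = out / "scores.csv"
    scores.to_csv(path, index=False)
    written.append(path)
    path = out / "score_summary.csv"
    score_summary(scores, speaker_pair).to_csv(path, index=False)
    written.append(path)
    return written


def run_symbolic_experiment(
    design: Design,
    fam_speaker,
    test_speaker,
    stimulus_design=None,
    codebook_sizes: tuple[int, int, int] = (20, 20, 10),
    seed: int = 0,
    label_noise: float = 0.0,
    score_modes: Sequence[str] = ("single", "cluster"),
    alphas: np.ndarray = DEFAULT_ALPHAS,
    thetas: np.ndarray = DEFAULT_THETAS,
    rho: float = 0.4,
    behavior_mode: str = "superpose",
    nmf_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """End-to-end experiment on symbolic label streams (no audio synthesis).

    Familiarization tokens, background and noise come from ``fam_speaker``;
    test sentences from ``test_speaker``. Returns the sentence-score table and
    one significance grid per score mode.
    """
    from .stimuli import StimulusDesign, WordSpec, generate_symbolic_set

    stimulus_design = stimulus_design or StimulusDesign(
        n_tokens=design.n_tokens, n_sentences_per_word=design.n_sentences_per_word
    )
    word_specs = _word_specs(design.words)
    fam_set = generate_symbolic_set(
        word_specs, fam_speaker, stimulus_design, codebook_sizes, seed, label_noise
    )
    if test_speaker.speaker_id == fam_speaker.speaker_id:
        test_set = fam_set
    else:
        test_set = generate_symbolic_set(
            word_specs, test_speaker, stimulus_design, codebook_sizes, seed + 1, label_noise
        )
    scores = score_label_streams(
        test_set["sentences"], fam_set["tokens"], fam_set["background"],
        fam_set["noise"], design, nmf_kwargs=nmf_kwargs,
    )
    sentence_ids = {
        wid: [sid for sid, _ in sents] for wid, sents in test_set["sentences"].items()
    }
    passages = assemble_passages(sentence_ids, design)
    grids = {
        mode: run_grid(
            passages, scores, score_mode=mode, alphas=alphas, thetas=thetas,
            rho=rho, mode=behavior_mode,
        )
        for mode in score_modes
    }
    return scores, grids


def run_audio_experiment(
    design: Design,
    fam_speaker,
    test_speaker,
    stimulus_design=None,
    codebook_sizes: tuple[int, int, int] = cb.DEFAULT_SIZES,
    seed: int = 0,
    score_modes: Sequence[str] = ("single", "cluster"),
    alphas: np.ndarray = DEFAULT_ALPHAS,
    thetas: np.ndarray = DEFAULT_THETAS,
    rho: float = 0.4,
    behavior_mode: str = "superpose",
    nmf_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """End-to-end experiment through the audio pipeline.

    Synthesizes both speakers' stimulus sets, extracts features, trains
    codebooks on the familiarization speaker's background, scores all test
    sentences under both memories and sweeps the {alpha, theta} grid.
    """
    from .stimuli import StimulusDesign, generate_stimulus_set

    stimulus_design = stimulus_design or StimulusDesign(
        n_tokens=design.n_tokens, n_sentences_per_word=design.n_sentences_per_word
    )
    word_specs = _word_specs(design.words)
    fam_stimuli = generate_stimulus_set(word_specs, fam_speaker, stimulus_design, seed)
    if test_speaker.speaker_id == fam_speaker.speaker_id:
        test_stimuli = fam_stimuli
    else:
        test_stimuli = generate_stimulus_set(
            word_specs, test_speaker, stimulus_design, seed + 1
        )
    scores = score_all_sentences(
        design, fam_stimuli, test_stimuli,
        codebook_sizes=codebook_sizes, codebook_seed=seed, nmf_kwargs=nmf_kwargs,
    )
    sentence_ids = {
        wid: sorted(scores.loc[scores.word_id == wid, "sentence_id"].unique())
        for wid in design.words
    }
    passages = assemble_passages(sentence_ids, design)
    grids = {
        mode: run_grid(
            passages, scores, score_mode=mode, alphas=alphas, thetas=thetas,
            rho=rho, mode=behavior_mode,
        )
        for mode in score_modes
    }
    return scores, grids


def _word_specs(word_ids: Sequence[str]):
    """WordSpecs for the given ids, using the default inventory where the ids
    match and synthesizing distinct templates otherwise."""
    from .stimuli import Segment, WordSpec, default_words

    defaults = {w.word_id: w for w in default_words()}
    specs = []
    for i, wid in enumerate(word_ids):
        if wid in defaults:
            specs.append(defaults[wid])
        else:
            specs.append(
                WordSpec(
                    wid,
                    (
                        Segment(70 + 10 * (i % 4), (900.0 + 180.0 * i, 2100.0 + 150.0 * i),
                                voiced=False, gain=0.5),
                        Segment(330 + 25 * i, (480.0 + 60.0 * i, 1050.0 + 110.0 * i)),
                    ),
                )
            )
    return specs


def hinton_plot(grid: pd.DataFrame, path) -> Path:
    """Hinton-style plot: rectangle area encodes significance per {alpha, theta}."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    sig = grid[grid.sign != SIGN_NONE]
    if not sig.empty:
        size = -np.log10(np.maximum(sig.p.to_numpy(), 1e-12))
        colors = np.where(sig.sign == SIGN_FAMILIAR, "black", "grey")
        ax.scatter(sig.alpha, sig.theta, s=8 * size, c=colors, marker="s")
    ax.set_xlabel(r"attention decay $\alpha$ (1/s)")
    ax.set_ylabel(r"experimenter threshold $\theta$")
    ax.set_xlim(grid.alpha.min(), grid.alpha.max())
    ax.set_ylim(grid.theta.min(), grid.theta.max())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
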