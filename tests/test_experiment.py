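import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hppsim import (
    Design,
    ParameterError,
    assemble_passages,
    export_results,
    mann_whitney_u,
    make_speaker_profile,
    run_grid,
    score_label_streams,
    welch_t,
)
from hppsim.stimuli import StimulusDesign, default_words, generate_symbolic_set

WORDS = ("frog", "doll", "duck", "ball")


def _design(**kwargs):
    defaults = dict(words=WORDS, n_sentences_per_word=2, n_passages_per_word=4,
                    passage_len=3, seed=7)
    defaults.update(kwargs)
    return Design(**defaults)


# ---------------------------------------------------------------------------
# statistics


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 labelings are as extreme

    def test_identical_samples(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_u([], [1.0])

    def test_matches_exhaustive_permutation_oracle(self):
        """Exact p equals brute-force enumeration of all group labelings."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            nx, ny = rng.integers(1, 7, size=2)
            pooled = rng.normal(size=nx + ny)  # continuous: no ties
            x, y = pooled[:nx], pooled[nx:]
            u_obs, p_obs = mann_whitney_u(x, y)

            def u_of(xs, ys):
                return sum(1.0 for a in xs for b in ys if a > b) + 0.5 * sum(
                    1.0 for a in xs for b in ys if a == b
                )

            stats = [
                u_of(pooled[list(c)], np.delete(pooled, list(c)))
                for c in itertools.combinations(range(nx + ny), nx)
            ]
            stats = np.asarray(stats)
            lo = np.mean(stats <= u_obs + 1e-12)
            hi = np.mean(stats >= u_obs - 1e-12)
            p_exact = min(1.0, 2.0 * min(lo, hi))
            assert p_obs == pytest.approx(p_exact, abs=1e-12)


class TestWelchT:
    def test_identical_samples_give_zero_t(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ParameterError):
            welch_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])

    def test_matches_direct_formula(self):
        """Statistic and p recomputed from the textbook formula to 1e-10."""
        rng = np.random.default_rng(29)
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(3, 20)))
            y = rng.normal(loc=0.4, size=int(rng.integers(3, 20)))
            t_obs, p_obs = welch_t(x, y)
            vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
            t_ref = (x.mean() - y.mean()) / math.sqrt(vx + vy)
            df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
            p_ref = 2.0 * scipy.stats.t.sf(abs(t_ref), df)
            assert t_obs == pytest.approx(t_ref, abs=1e-10)
            assert p_obs == pytest.approx(p_ref, abs=1e-10)


# ---------------------------------------------------------------------------
# sentence scoring (symbolic route)


@pytest.fixture(scope="module")
def scored():
    speaker = make_speaker_profile("S1", 1.0, 0.0, 3)
    design = _design()
    sd = StimulusDesign(n_tokens=3, n_sentences_per_word=2, n_background=8)
    sset = generate_symbolic_set(default_words(), speaker, sd, (10, 10, 8), seed=5)
    scores = score_label_streams(
        sset["sentences"], sset["tokens"], sset["background"], sset["noise"], design
    )
    return design, sset, scores


def test_each_sentence_scored_once_per_familiarization_set(scored):
    design, sset, scores = scored
    assert len(scores) == 16  # 8 sentences x 2 familiarization sets
    per_sentence = scores.groupby("sentence_id").condition.agg(set)
    assert all(s == {"familiar", "novel"} for s in per_sentence)
    # condition assignment follows the word partition
    for row in scores.itertuples():
        expected = "familiar" if design.fam_set_of(row.word_id) == row.fam_set else "novel"
        assert row.condition == expected


def test_scores_are_valid_percentages(scored):
    _, _, scores = scored
    for col in ("single_score_pct", "cluster_score_pct"):
        assert scores[col].between(0, 100).all()
    assert (scores.cluster_score_pct >= scores.single_score_pct - 1e-9).all()


# ---------------------------------------------------------------------------
# passages and grid


def test_assemble_passages_counts_and_determinism():
    design = _design(n_passages_per_word=5, passage_len=6)
    ids = {w: [f"{w}_{i}" for i in range(4)] for w in WORDS}
    a = assemble_passages(ids, design)
    b = assemble_passages(ids, design)
    assert a == b
    for w in WORDS:
        assert len(a[w]) == 5
        assert all(len(p) == 6 and all(s.startswith(w) for s in p) for p in a[w])


def test_assemble_passages_rejects_missing_word():
    with pytest.raises(ParameterError):
        assemble_passages({"frog": ["frog_0"]}, _design())


def _fake_scores(score_fam=40.0, score_nov=10.0, duration=3.0, jitter=0.0, seed=0):
    """A synthetic sentence-score table with a built-in familiarity advantage."""
    rng = np.random.default_rng(seed)
    rows = []
    for w in WORDS:
        for i in range(4):
            sid = f"{w}_{i}"
            for condition, base in (("familiar", score_fam), ("novel", score_nov)):
                s = max(base + rng.normal(0, jitter), 0.0) if jitter else base
                rows.append(
                    dict(sentence_id=sid, word_id=w, fam_set=0, condition=condition,
                         single_score_pct=s, cluster_score_pct=s,
                         duration_s=duration + (0.2 * i if jitter else 0.0))
                )
    return pd.DataFrame(rows)


def _passages():
    ids = {w: [f"{w}_{i}" for i in range(4)] for w in WORDS}
    return assemble_passages(ids, _design(n_passages_per_word=6, passage_len=6))


def test_grid_shape_and_sign_coherence():
    scores = _fake_scores(jitter=6.0, seed=1)
    alphas = np.arange(0.05, 0.31, 0.05)
    thetas = np.arange(0.1, 1.2, 0.2)
    grid = run_grid(_passages(), scores, "cluster", alphas, thetas)
    assert len(grid) == alphas.size * thetas.size
    sig = grid[grid.sign != "none"]
    assert (sig.p < 0.05).all()
    assert all(
        (row.sign == "familiar") == (row.mean_fam > row.mean_nov)
        for row in sig.itertuples()
    )


def test_tiny_theta_gives_full_durations_and_no_preference():
    scores = _fake_scores(jitter=6.0, seed=2)
    grid = run_grid(
        _passages(), scores, "cluster", np.array([0.1]), np.array([1e-6])
    )
    row = grid.iloc[0]
    # every passage is listened to fully; durations are identical across
    # conditions by construction, so no preference can emerge
    assert row.mean_fam == pytest.approx(row.mean_nov)
    assert row.sign == "none"


def test_familiarity_advantage_produces_familiar_region():
    scores = _fake_scores(score_fam=50.0, score_nov=5.0, jitter=3.0, seed=3)
    grid = run_grid(
        _passages(), scores, "cluster",
        np.arange(0.05, 0.31, 0.05), np.arange(0.1, 1.2, 0.1),
    )
    assert (grid.sign == "familiar").sum() > 0
    assert (grid.sign == "novel").sum() == 0


def test_paired_passages_enter_both_conditions():
    from hppsim.experiment import _passage_arrays

    scores = _fake_scores()
    arrays = _passage_arrays(_passages(), scores, "cluster")
    assert len(arrays) == 4 * 6  # every passage yields a familiar AND novel trace
    for d, fam, nov in arrays:
        assert d.shape == fam.shape == nov.shape == (6,)
        assert np.all(fam == 40.0) and np.all(nov == 10.0)


def test_export_results_files_and_idempotence(tmp_path):
    scores = _fake_scores(jitter=4.0, seed=4)
    grid = run_grid(
        _passages(), scores, "cluster", np.array([0.1, 0.2]), np.array([0.3, 0.5])
    )
    out1 = tmp_path / "a"
    out2 = tmp_path / "b"
    export_results({"cluster": grid}, scores, out1)
    export_results({"cluster": grid}, scores, out2)
    for name in ("grid_cluster.csv", "scores.csv", "score_summary.csv"):
        assert (out1 / name).exists()
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    assert len(pd.read_csv(out1 / "grid_cluster.csv")) == 4


def test_design_partition_validation():
    with pytest.raises(ParameterError):
        Design(words=WORDS, familiarization_sets=(("frog", "doll"), ("frog", "ball")))
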