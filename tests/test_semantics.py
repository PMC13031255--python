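"""Summary-vs-segment similarity scores against hand-computed oracles."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compslide.semantics import (
    EmbeddingTable,
    MeanPoolEncoder,
    ScoredSummary,
    VocabularyError,
    contextual_similarity,
    correlate_measures,
    cosine,
    heard_segment_score,
    pentile_similarity_profile,
    score_summary,
    tokenize,
    written_summary_score,
)
from compslide.simulate import make_toy_embeddings, simulate_summary


class TestTokenize:
    def test_case_and_punctuation(self):
        assert tokenize("The cat, the CAT!") == ["the", "cat", "the", "cat"]

    def test_empty(self):
        assert tokenize("") == []

    @settings(max_examples=100, deadline=None)
    @given(st.text(max_size=80))
    def test_matches_reference_regex(self, text):
        assert tokenize(text) == re.findall(r"[a-z0-9']+", text.lower())


class TestCosine:
    def test_self_is_one(self):
        v = np.array([3.0, 4.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == pytest.approx(0.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u, v = rng.standard_normal(5), rng.standard_normal(5)
            expected = float(u @ v) / float(np.sqrt(u @ u) * np.sqrt(v @ v))
            assert cosine(u, v) == pytest.approx(expected)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(3), np.ones(3))


class TestWrittenSummaryScore:
    def test_exact_word_match_scores_one(self, toy_table_2d):
        assert written_summary_score(["dog"], ["dog", "rain"], toy_table_2d) == pytest.approx(1.0)

    def test_empty_summary_scores_zero(self, toy_table_2d):
        assert written_summary_score([], ["dog"], toy_table_2d) == 0.0

    def test_hand_computed_toy_case(self, toy_table_2d):
        # cat.dog = 0.8, rain.dog = 0 -> 0.8 + 0.0
        score = written_summary_score(["cat", "rain"], ["dog"], toy_table_2d)
        assert score == pytest.approx(0.8)

    def test_additive_over_summary_words(self, toy_table_2d):
        base = written_summary_score(["cat"], ["dog", "rain"], toy_table_2d)
        extended = written_summary_score(["cat", "rain"], ["dog", "rain"], toy_table_2d)
        assert extended == pytest.approx(base + 1.0)  # rain matches itself

    def test_duplication_changes_written_but_not_heard(self, toy_table_2d):
        seg = ["dog", "rain"]
        once = written_summary_score(["cat"], seg, toy_table_2d)
        twice = written_summary_score(["cat", "cat"], seg, toy_table_2d)
        assert twice == pytest.approx(2 * once)
        assert heard_segment_score(["cat"], seg, toy_table_2d) == pytest.approx(
            heard_segment_score(["cat", "cat"], seg, toy_table_2d)
        )

    def test_oov_words_skipped(self, toy_table_2d):
        with_oov = written_summary_score(["cat", "zebra"], ["dog"], toy_table_2d)
        assert with_oov == pytest.approx(0.8)

    def test_no_invocab_segment_rejected(self, toy_table_2d):
        with pytest.raises(VocabularyError):
            written_summary_score(["cat"], ["zebra"], toy_table_2d)


class TestHeardSegmentScore:
    def test_full_coverage_scores_one(self, toy_table_2d):
        seg = ["dog", "rain", "cat"]
        assert heard_segment_score(seg, seg, toy_table_2d) == pytest.approx(1.0)

    def test_orthogonal_summary_scores_zero(self, toy_table_2d):
        assert heard_segment_score(["rain"], ["dog"], toy_table_2d) == pytest.approx(0.0)

    def test_hand_computed_toy_case(self, toy_table_2d):
        # dog.cat = 0.8, rain.cat = 0.6 -> mean 0.7
        score = heard_segment_score(["cat"], ["dog", "rain"], toy_table_2d)
        assert score == pytest.approx(0.7)

    def test_no_invocab_summary_rejected(self, toy_table_2d):
        with pytest.raises(VocabularyError):
            heard_segment_score(["zebra"], ["dog"], toy_table_2d)


class TestContextualSimilarity:
    def test_identical_texts_score_one(self, toy_table_2d):
        enc = MeanPoolEncoder(toy_table_2d)
        assert contextual_similarity("dog rain", "dog rain", enc) == pytest.approx(1.0)

    def test_symmetry(self, toy_table_2d):
        enc = MeanPoolEncoder(toy_table_2d)
        assert contextual_similarity("dog", "cat rain", enc) == pytest.approx(
            contextual_similarity("cat rain", "dog", enc)
        )

    def test_mean_pool_matches_hand_computation(self, toy_table_2d):
        enc = MeanPoolEncoder(toy_table_2d)
        u = (np.array([1.0, 0.0]) + np.array([0.0, 1.0])) / 2  # dog, rain
        v = np.array([0.8, 0.6])  # cat
        expected = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        assert contextual_similarity("dog rain", "cat", enc) == pytest.approx(expected)

    def test_empty_text_rejected(self, toy_table_2d):
        with pytest.raises(ValueError):
            contextual_similarity("", "dog", MeanPoolEncoder(toy_table_2d))


class TestPentileProfile:
    def test_bin_sizes_for_23_words(self, toy_table_2d):
        segment = ["dog", "cat", "rain"] * 8
        segment = segment[:23]
        profile = pentile_similarity_profile(["dog"], segment, "heard", toy_table_2d)
        assert len(profile) == 5

    def test_summary_equal_to_segment_gives_all_ones(self, toy_table_2d):
        segment = ["dog", "cat", "rain", "dog", "cat", "rain"]
        profile = pentile_similarity_profile(segment, segment, "heard", toy_table_2d)
        assert np.allclose(profile, 1.0)

    def test_profile_peaks_where_summary_vocabulary_lives(self):
        # orthogonal one-hot vocabulary: words elsewhere share no direction
        vocab = {f"w{i}": np.eye(25)[i] for i in range(25)}
        emb = EmbeddingTable(vocab)
        segment = [f"w{i}" for i in range(25)]
        summary = ["w20", "w21", "w22", "w23", "w24"]  # pentile 5 only
        profile = pentile_similarity_profile(summary, segment, "heard", emb)
        assert np.argmax(profile) == 4

    def test_short_segment_rejected(self, toy_table_2d):
        with pytest.raises(Exception):
            pentile_similarity_profile(["dog"], ["dog", "cat"], "heard", toy_table_2d)


class TestCorrelateMeasures:
    @staticmethod
    def _scores(rng, n=30, tie_contextual_to_written=False):
        out = []
        for i in range(n):
            w = rng.random()
            out.append(
                ScoredSummary(
                    trial_id=f"t{i}",
                    written_summary_score=w,
                    heard_segment_score=rng.random(),
                    contextual_score=w if tie_contextual_to_written else rng.random(),
                    n_summary_words=5,
                    n_segment_words=20,
                )
            )
        return out

    def test_unit_diagonal_and_symmetry(self):
        m = correlate_measures(self._scores(np.random.default_rng(0)))
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_identical_measures_correlate_perfectly(self):
        m = correlate_measures(self._scores(np.random.default_rng(1), tie_contextual_to_written=True))
        assert m.loc["written", "contextual"] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        scores = self._scores(np.random.default_rng(2))
        m = correlate_measures(scores)
        w = np.array([s.written_summary_score for s in scores])
        h = np.array([s.heard_segment_score for s in scores])
        expected = np.mean((w - w.mean()) * (h - h.mean())) / (w.std() * h.std())
        assert m.loc["written", "heard"] == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        scores = [
            ScoredSummary(f"t{i}", 1.0, float(i), float(i), 1, 1) for i in range(5)
        ]
        with pytest.raises(ValueError, match="written"):
            correlate_measures(scores)


class TestWord2VecFormat:
    def test_round_trip_is_byte_identical(self, tmp_path):
        emb = make_toy_embeddings(["alpha", "beta", "gamma"], dim=5, seed=4)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        emb.to_word2vec(p1)
        EmbeddingTable.from_word2vec(p1).to_word2vec(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("2 3\nonly 0.1 0.2 0.3\n")
        with pytest.raises(ValueError):
            EmbeddingTable.from_word2vec(p)


class TestSimulatorScoreCoupling:
    def test_scores_rise_with_comprehension(self):
        """Across simulated trials with rising comprehension, all three scores
        should rise in rank terms."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        vocab = [f"tok{i:03d}" for i in range(120)]
        emb = make_toy_embeddings(vocab, dim=16, seed=5)
        comp = np.linspace(0.1, 0.95, 200)
        rows = []
        for i, c in enumerate(comp):
            segment = list(rng.choice(vocab, size=40, replace=True))
            summary = simulate_summary(segment, c, recency_bias=1.0, seed=1000 + i)
            s = score_summary(f"t{i}", " ".join(summary), " ".join(segment), emb)
            rows.append((s.written_summary_score, s.heard_segment_score, s.contextual_score))
        rows = np.array(rows)
        for col in range(3):
            assert spearmanr(comp, rows[:, col]).statistic > 0

    def test_recency_bias_tilts_pentile_profile_upward(self):
        rng = np.random.default_rng(6)
        vocab = [f"tok{i:03d}" for i in range(200)]
        emb = make_toy_embeddings(vocab, dim=16, seed=6)
        slopes = []
        for i in range(60):
            segment = list(rng.choice(vocab, size=50, replace=False))
            summary = simulate_summary(segment, 0.3, recency_bias=4.0, seed=i)
            profile = pentile_similarity_profile(summary, segment, "heard", emb)
            slopes.append(np.polyfit(np.arange(5), profile, 1)[0])
        assert np.mean(slopes) > 0
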