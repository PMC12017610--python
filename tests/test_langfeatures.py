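"""Transcript normalization, counts, timing, and word mover's distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moodspeech.langfeatures import (
    EmbeddingTable,
    LanguageFeatureExtractor,
    ReferenceStory,
    TimedTranscript,
    Word,
    count_features,
    normalize_tokens,
    timing_scores,
    word_movers_distance,
)
from .oracles import wmd_enumeration_oracle

TOY_WORDS = ["river", "storm", "bridge", "car", "doctor", "home"]


def _transcript(tokens, start=0.0, step=0.5, dur=0.3, task_start=0.0):
    words = [Word(t, start + i * step, start + i * step + dur)
             for i, t in enumerate(tokens)]
    return TimedTranscript(words=words, task_start_s=task_start)


class TestNormalization:
    def test_punctuation_and_case_stripped(self):
        assert normalize_tokens("La macchina, correva!") == ["la", "macchina", "correva"]

    def test_empty_text(self):
        assert normalize_tokens("") == []

    @settings(derandomize=True, max_examples=50)
    @given(st.text(max_size=60))
    def test_idempotent(self, text):
        once = normalize_tokens(text)
        assert normalize_tokens(" ".join(once)) == once


class TestTranscript:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TimedTranscript(words=[Word("a", 0.0, 0.6), Word("b", 0.5, 0.9)])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            TimedTranscript(words=[Word("a", 1.0, 1.2), Word("b", 0.0, 0.4)])

    def test_json_roundtrip(self):
        t = _transcript(["uno", "due"])
        assert TimedTranscript.from_json(t.to_json()) == t


class TestCounts:
    story = ReferenceStory("a b c")

    def test_type_level_membership_with_multiplicity(self):
        n_words, n_matched = count_features(_transcript(list("abbz")), self.story)
        assert (n_words, n_matched) == (4, 3)

    def test_empty_transcript(self):
        assert count_features(TimedTranscript(words=[]), self.story) == (0, 0)

    def test_verbatim_recall_matches_everything(self):
        n_words, n_matched = count_features(_transcript(list("abc")), self.story)
        assert n_matched == n_words

    def test_matching_is_normalized(self):
        n_words, n_matched = count_features(_transcript(["A!", "b,"]), self.story)
        assert (n_words, n_matched) == (2, 2)


class TestTiming:
    def test_latency_is_first_onset_minus_task_start(self):
        latency, _ = timing_scores(_transcript(["x"], start=2.30))
        assert latency == pytest.approx(2.30)

    def test_mean_intraword_onset_to_onset(self):
        t = TimedTranscript(words=[Word("a", 0.0, 0.2), Word("b", 0.5, 0.7),
                                   Word("c", 1.5, 1.7)])
        _, intra = timing_scores(t)
        assert intra == pytest.approx(0.75)

    def test_gap_convention(self):
        t = TimedTranscript(words=[Word("a", 0.0, 0.2), Word("b", 0.5, 0.7)])
        _, intra = timing_scores(t, convention="gap")
        assert intra == pytest.approx(0.3)

    def test_single_word_has_latency_but_no_intraword(self):
        latency, intra = timing_scores(_transcript(["solo"], start=1.0))
        assert latency == pytest.approx(1.0)
        assert np.isnan(intra)

    def test_empty_transcript_all_missing(self):
        latency, intra = timing_scores(TimedTranscript(words=[]))
        assert np.isnan(latency) and np.isnan(intra)


class TestWMD:
    def test_identity_is_zero(self, toy_embedding):
        doc = ["river", "storm", "storm"]
        wmd, *_ = word_movers_distance(doc, list(doc), toy_embedding)
        assert wmd == pytest.approx(0.0, abs=1e-9)

    def test_single_mass_transport_is_ground_distance(self):
        emb = EmbeddingTable({"x": np.array([0.0, 0.0]), "y": np.array([2.0, 0.0])})
        wmd, *_ = word_movers_distance(["x"], ["y"], emb)
        assert wmd == pytest.approx(2.0)

    def test_symmetry_and_nonnegativity(self, toy_embedding):
        rng = np.random.default_rng(0)
        for _ in range(10):
            doc = list(rng.choice(TOY_WORDS, size=rng.integers(1, 5)))
            ref = list(rng.choice(TOY_WORDS, size=rng.integers(1, 5)))
            d1, *_ = word_movers_distance(doc, ref, toy_embedding)
            d2, *_ = word_movers_distance(ref, doc, toy_embedding)
            assert d1 >= 0
            assert d1 == pytest.approx(d2, abs=1e-9)

    def test_matches_enumeration_oracle(self, toy_embedding):
        vectors = {w: toy_embedding[w] for w in TOY_WORDS}
        rng = np.random.default_rng(1)
        for _ in range(20):
            doc = list(rng.choice(TOY_WORDS, size=rng.integers(1, 6)))
            ref = list(rng.choice(TOY_WORDS, size=rng.integers(1, 6)))
            wmd, *_ = word_movers_distance(doc, ref, toy_embedding)
            oracle = wmd_enumeration_oracle(doc, ref, vectors)
            assert wmd == pytest.approx(oracle, abs=1e-6)

    def test_triangle_inequality_spot_check(self, toy_embedding):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b, c = (list(rng.choice(TOY_WORDS, size=3)) for _ in range(3))
            dab, *_ = word_movers_distance(a, b, toy_embedding)
            dbc, *_ = word_movers_distance(b, c, toy_embedding)
            dac, *_ = word_movers_distance(a, c, toy_embedding)
            assert dac <= dab + dbc + 1e-9

    def test_oov_side_reports_missing_with_counts(self, toy_embedding):
        wmd, doc_oov, ref_oov = word_movers_distance(
            ["notinvocab"], ["river"], toy_embedding
        )
        assert np.isnan(wmd)
        assert (doc_oov, ref_oov) == (1, 0)

    def test_shared_added_word_bounded_perturbation(self, toy_embedding):
        doc = ["river", "storm"]
        ref = ["bridge", "car"]
        base, *_ = word_movers_distance(doc, ref, toy_embedding)
        vecs = np.stack([toy_embedding[w] for w in TOY_WORDS])
        max_dist = max(
            np.linalg.norm(u - v) for u in vecs for v in vecs
        )
        added_mass = 1 / 3  # one token added to each two-token side
        pert, *_ = word_movers_distance(doc + ["home"], ref + ["home"], toy_embedding)
        assert pert <= base + added_mass * max_dist + 1e-9


class TestEmbeddingIO:
    def test_roundtrip_with_header(self, tmp_path, toy_embedding):
        path = tmp_path / "emb.txt"
        toy_embedding.write_text(path)
        back = EmbeddingTable.read_text(path)
        assert back.vocabulary == toy_embedding.vocabulary
        for w in TOY_WORDS:
            assert np.allclose(back[w], toy_embedding[w], atol=1e-6)

    def test_headerless_format(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("a 1 0\nb 0 1\n")
        emb = EmbeddingTable.read_text(path)
        assert len(emb) == 2 and emb.dim == 2

    def test_duplicate_word_rejected(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("2 2\na 1 0\na 0 1\n")
        with pytest.raises(ValueError, match="duplicate"):
            EmbeddingTable.read_text(path)

    def test_inconsistent_dimension_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingTable({"a": np.ones(2), "b": np.ones(3)})


class TestExtractor:
    def test_full_panel_on_simple_transcript(self, toy_embedding):
        story = ReferenceStory("river storm bridge")
        extractor = LanguageFeatureExtractor(story=story, embeddings=toy_embedding)
        feats = extractor.extract(_transcript(["river", "home"], start=0.4))
        assert feats["n_words"] == 2
        assert feats["n_matched"] == 1
        assert feats["latency_s"] == pytest.approx(0.4)
        assert np.isfinite(feats["wmd"])

    def test_transform_returns_one_row_per_transcript(self, toy_embedding):
        story = ReferenceStory("river storm")
        extractor = LanguageFeatureExtractor(story=story, embeddings=toy_embedding)
        frame = extractor.transform([_transcript(["river"]), _transcript(["storm"])])
        assert len(frame) == 2
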