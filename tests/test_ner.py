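import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from medireader import ner


def brute_force_crf(emissions, transitions):
    """Exhaustive enumeration oracle over all T^L tag paths."""
    L, T = emissions.shape
    start, stop = T, T + 1
    scores, paths = [], []
    for path in itertools.product(range(T), repeat=L):
        s = transitions[start, path[0]] + emissions[0, path[0]]
        for t in range(1, L):
            s += transitions[path[t - 1], path[t]] + emissions[t, path[t]]
        s += transitions[path[-1], stop]
        scores.append(s)
        paths.append(path)
    best = int(np.argmax(scores))
    return logsumexp(scores), paths[best], scores[best]


class TestCRF:
    def test_zero_scores_partition_is_L_log_T(self):
        for L, T in [(1, 2), (3, 3), (4, 2)]:
            em = np.zeros((L, T))
            tr = np.zeros((T + 2, T + 2))
            assert ner.crf_log_partition(em, tr) == pytest.approx(
                L * np.log(T), abs=1e-12)

    def test_zero_scores_viterbi_ties_to_smallest_path(self):
        path, score = ner.crf_viterbi(np.zeros((3, 3)), np.zeros((5, 5)))
        assert path == [0, 0, 0] and score == 0.0

    def test_single_token_reduction(self):
        rng = np.random.default_rng(0)
        em = rng.normal(size=(1, 4))
        tr = rng.normal(size=(6, 6))
        expected = logsumexp(tr[4, :4] + em[0] + tr[:4, 5])
        assert ner.crf_log_partition(em, tr) == pytest.approx(expected,
                                                              abs=1e-10)

    def test_forward_and_viterbi_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            L = int(rng.integers(1, 5))
            T = int(rng.integers(1, 5))
            em = rng.normal(size=(L, T)) * 2
            tr = rng.normal(size=(T + 2, T + 2)) * 2
            lz, bpath, bscore = brute_force_crf(em, tr)
            assert ner.crf_log_partition(em, tr) == pytest.approx(lz, abs=1e-8)
            vpath, vscore = ner.crf_viterbi(em, tr)
            assert vscore == pytest.approx(bscore, abs=1e-8)
            assert tuple(vpath) == bpath

    def test_partition_dominates_best_path(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            L, T = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            em = rng.normal(size=(L, T))
            tr = rng.normal(size=(T + 2, T + 2))
            _, best = ner.crf_viterbi(em, tr)
            assert ner.crf_log_partition(em, tr) >= best - 1e-12

    def test_viterbi_beats_random_paths(self):
        rng = np.random.default_rng(3)
        em = rng.normal(size=(6, 4))
        tr = rng.normal(size=(6, 6))
        _, best = ner.crf_viterbi(em, tr)
        for _ in range(100):
            path = rng.integers(0, 4, size=6)
            s = tr[4, path[0]] + em[0, path[0]]
            for t in range(1, 6):
                s += tr[path[t - 1], path[t]] + em[t, path[t]]
            s += tr[path[-1], 5]
            assert best >= s - 1e-12

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            ner.crf_log_partition(np.array([[np.nan, 0.0]]), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ner.crf_viterbi(np.zeros((2, 2)), np.full((4, 4), np.inf))


class TestTokenizerAndCorpus:
    def test_offsets_reconstruct_tokens(self):
        text = "Pt c/o severe headache, started lisinopril 10mg."
        for tok, s, e in ner.tokenize_with_offsets(text):
            assert text[s:e] == tok

    def test_conll_round_trip(self, tmp_path, ner_corpus):
        sentences, _ = ner_corpus
        p = tmp_path / "c.conll"
        ner.write_conll(sentences, p)
        loaded = ner.read_conll(p)
        assert len(loaded) == len(sentences)
        for a, b in zip(loaded, sentences):
            assert a.tokens == b.tokens and a.tags == b.tags

    def test_invalid_bio_sequence_rejected(self):
        with pytest.raises(ValueError):
            ner.TaggedSentence(["a", "b"], ["O", "I-Drug"])
        with pytest.raises(ValueError):
            ner.TaggedSentence(["a", "b"], ["B-Drug", "I-Test"])

    def test_tags_to_spans(self):
        tags = ["B-Drug", "I-Drug", "O", "B-Test", "B-Disease"]
        assert ner.tags_to_spans(tags) == [("Drug", 0, 2), ("Test", 3, 4),
                                           ("Disease", 4, 5)]


class TestTagger:
    def test_memorizes_fixture_corpus(self, trained_tagger, ner_corpus):
        """A correct implementation must memorize a 30-sentence corpus."""
        sentences, _ = ner_corpus
        pred = [trained_tagger.predict_tags(s.tokens) for s in sentences]
        assert ner.entity_f1([s.tags for s in sentences], pred) == 1.0

    def test_loss_decreases(self, trained_tagger):
        hist = trained_tagger.loss_history
        assert hist[-1] < hist[0]

    def test_same_seed_same_predictions(self, ner_corpus):
        sentences, _ = ner_corpus
        cfg = ner.TaggerConfig(seed=11, epochs=3)
        m1 = ner.train_tagger(sentences[:8], cfg)
        m2 = ner.train_tagger(sentences[:8], ner.TaggerConfig(seed=11,
                                                              epochs=3))
        held_out = sentences[10]
        assert m1.predict_tags(held_out.tokens) == \
            m2.predict_tags(held_out.tokens)

    def test_empty_text_no_mentions(self, trained_tagger):
        assert ner.tag(trained_tagger, "") == []

    def test_mention_offsets_valid(self, trained_tagger, ner_corpus):
        sentences, _ = ner_corpus
        text = " ".join(sentences[0].tokens)
        for m in ner.tag(trained_tagger, text):
            assert 0 <= m.start < m.end <= len(text)
            assert text[m.start:m.end] == m.surface

    def test_memorized_sentence_yields_gold_mentions(self, trained_tagger,
                                                     ner_corpus):
        sentences, gold = ner_corpus
        sent = sentences[0]
        text = " ".join(sent.tokens)
        found = {(m.surface, m.type) for m in ner.tag(trained_tagger, text)}
        expected = {(g["surface"], g["type"]) for g in gold
                    if g["sentence"] == 0}
        assert expected <= found

    def test_save_load_round_trip(self, trained_tagger, ner_corpus, tmp_path):
        sentences, _ = ner_corpus
        p = tmp_path / "model.json"
        trained_tagger.save(p)
        loaded = ner.TaggerModel.load(p)
        for s in sentences[:5]:
            assert loaded.predict_tags(s.tokens) == \
                trained_tagger.predict_tags(s.tokens)

    def test_constrained_decoding_emits_valid_bio(self, trained_tagger,
                                                  ner_corpus):
        sentences, _ = ner_corpus
        for s in sentences[:10]:
            tags = trained_tagger.predict_tags(s.tokens)
            ner.TaggedSentence(s.tokens, tags)   # raises if BIO-invalid

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            ner.train_tagger([], ner.TaggerConfig())

    def test_unknown_tag_rejected(self):
        sent = ner.TaggedSentence.__new__(ner.TaggedSentence)
        sent.tokens = ["x"]
        sent.tags = ["B-Alien"]
        sent.char_offsets = None
        with pytest.raises(ValueError):
            ner.train_tagger([sent], ner.TaggerConfig(epochs=1))
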