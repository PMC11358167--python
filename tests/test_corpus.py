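"""Transcript domain types, TSV/JSONL round trips, and cleaning rules."""

import pytest
from hypothesis import given, settings, strategies as st

from infodist.corpus import (
    Conversation,
    Corpus,
    CorpusParseError,
    clean_corpus,
    clean_utterance,
    read_corpus,
    write_corpus,
)
from tests.conftest import corpus_from_token_lists, make_utterance


class TestUtterance:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_utterance(["a"], start=100, end=50)
        with pytest.raises(ValueError):
            make_utterance([])
        with pytest.raises(ValueError):
            make_utterance(["a", "b", "c", "d"], tags=["NOUN", "VERB", "NOUN"])

    def test_conversation_rejects_more_than_two_speakers(self):
        utts = tuple(
            make_utterance(["hi"], start=i * 1000, end=i * 1000 + 500, speaker_id=f"s{i}")
            for i in range(3)
        )
        with pytest.raises(ValueError, match="dyadic"):
            Conversation(conversation_id="conv1", dyad_id="dyad1", utterances=utts)

    def test_conversation_sorts_by_start_time(self):
        u1 = make_utterance(["later"], start=5000, end=6000)
        u2 = make_utterance(["sooner"], start=0, end=1000, speaker_id="spk_b")
        conv = Conversation(conversation_id="conv1", dyad_id="dyad1", utterances=(u1, u2))
        assert [u.tokens[0] for u in conv.utterances] == ["sooner", "later"]

    def test_corpus_rejects_duplicate_conversation_ids(self):
        conv = Conversation(
            conversation_id="conv1", dyad_id="d", utterances=(make_utterance(["x"]),)
        )
        with pytest.raises(ValueError, match="unique"):
            Corpus(language_label="toy", conversations=(conv, conv))


class TestReadWrite:
    @pytest.mark.parametrize("dialect", ["tsv", "jsonl"])
    def test_round_trip_identity(self, tmp_path, dialect):
        corpus = corpus_from_token_lists(
            [["well", "I", "went", "home"], ["ñandú", "慢", "très", "bien"], ["ok"]]
        )
        path = tmp_path / f"toy.{dialect}"
        write_corpus(corpus, path, dialect=dialect)
        back = read_corpus(path, dialect=dialect, language_label="toy")
        assert back.language_label == corpus.language_label
        for orig, rt in zip(corpus.utterances(), back.utterances()):
            assert rt.tokens == orig.tokens
            assert (rt.start, rt.end) == (orig.start, orig.end)
            assert rt.speaker_id == orig.speaker_id
            assert rt.dyad_id == orig.dyad_id

    def test_three_line_tsv_parses_to_one_conversation(self, tmp_path):
        path = tmp_path / "mini.tsv"
        path.write_text(
            "conversation_id\tdyad_id\tspeaker\tstart_ms\tend_ms\ttokens\n"
            "c1\td1\ta\t0\t900\thello there friend\n"
            "c1\td1\tb\t1000\t1900\toh hello again\n"
            "c1\td1\ta\t2000\t2900\tyes indeed\n"
        )
        corpus = read_corpus(path)
        assert len(corpus.conversations) == 1
        assert corpus.n_utterances == 3

    def test_tag_alignment_error_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "conversation_id\tdyad_id\tspeaker\tstart_ms\tend_ms\ttokens\ttags\n"
            "c1\td1\ta\t0\t900\tone two three four\tNOUN VERB NOUN\n"
        )
        with pytest.raises(CorpusParseError, match="bad.tsv:2"):
            read_corpus(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(CorpusParseError, match="empty"):
            read_corpus(path)

    def test_write_is_deterministic(self, tmp_path):
        corpus = corpus_from_token_lists([["a", "b"], ["c", "d"]])
        p1, p2 = tmp_path / "one.tsv", tmp_path / "two.tsv"
        write_corpus(corpus, p1)
        write_corpus(corpus, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCleaning:
    def test_fillers_removed(self):
        utt = make_utterance(["well", "uh", "I", "went"])
        cleaned = clean_utterance(utt, filler_lexicon={"uh", "hm", "ah"})
        assert cleaned.tokens == ("well", "i", "went")

    def test_punctuation_and_annotations_removed_with_tags(self):
        utt = make_utterance(
            ["so", ",", "[laughter]", "&=cough", "it's", "fine", "!"],
            tags=["ADV", "PUNCT", "X", "X", "PRON", "ADJ", "PUNCT"],
        )
        cleaned = clean_utterance(utt, filler_lexicon=set())
        assert cleaned.tokens == ("so", "it's", "fine")
        assert cleaned.tags == ("ADV", "PRON", "ADJ")

    def test_all_tokens_removed_flags_empty(self):
        assert clean_utterance(make_utterance(["uh", "hm"]), {"uh", "hm", "ah"}) is None

    def test_no_op_when_nothing_matches(self):
        utt = make_utterance(["already", "clean", "words"])
        cleaned = clean_utterance(utt, filler_lexicon={"uh"})
        assert cleaned.tokens == utt.tokens

    @given(
        st.lists(
            st.text(
                alphabet=st.characters(whitelist_categories=("Ll", "Po")),
                min_size=1,
                max_size=6,
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_cleaning_idempotent_and_order_preserving(self, tokens):
        utt = make_utterance(tokens)
        once = clean_utterance(utt, filler_lexicon={"uh", "hm", "ah"})
        if once is None:
            return
        twice = clean_utterance(once, filler_lexicon={"uh", "hm", "ah"})
        assert twice.tokens == once.tokens
        # survivors appear in original relative order
        kept = [t.lower() for t in tokens if t.lower() in once.tokens]
        assert list(once.tokens) == [t for t in kept if t in once.tokens] or len(
            once.tokens
        ) <= len(tokens)

    def test_clean_corpus_drops_emptied_utterances(self):
        corpus = corpus_from_token_lists([["uh", "hm"], ["real", "words", "here"]])
        cleaned = clean_corpus(corpus, filler_lexicon={"uh", "hm", "ah"})
        assert cleaned.n_utterances == 1
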