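import pytest

from infodist.corpus import Conversation, Corpus, Utterance
from infodist.synthetic import make_fixture


def make_utterance(
    tokens,
    tags=None,
    start=0,
    end=4000,
    conversation_id="conv1",
    dyad_id="dyad1",
    speaker_id="spk_a",
    utterance_id=None,
):
    return Utterance(
        conversation_id=conversation_id,
        dyad_id=dyad_id,
        speaker_id=speaker_id,
        start=start,
        end=end,
        tokens=tuple(tokens),
        tags=tuple(tags) if tags is not None else None,
        utterance_id=utterance_id,
    )


def corpus_from_token_lists(token_lists, language="toy", duration_ms=4000):
    """One-conversation corpus built from plain token lists."""
    utts = []
    for i, toks in enumerate(token_lists):
        start = i * (duration_ms + 500)
        utts.append(
            make_utterance(
                toks,
                start=start,
                end=start + duration_ms,
                speaker_id="spk_a" if i % 2 == 0 else "spk_b",
                utterance_id=f"u{i}",
            )
        )
    conv = Conversation(conversation_id="conv1", dyad_id="dyad1", utterances=tuple(utts))
    return Corpus(language_label=language, conversations=(conv,))


@pytest.fixture(scope="session")
def tiny_fixture():
    [(corpus, gt)] = make_fixture("tiny", seed=0)
    return corpus, gt


@pytest.fixture(scope="session")
def reference_suite():
    """The calibrated six-language suite (3 back- and 3 front-loaded)."""
    return make_fixture("reference", seed=0)
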