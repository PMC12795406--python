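import numpy as np
import pytest

from rolepred.corpus import AnnotatedUtterance, ArgumentSpan, Corpus, Nominality, Role
from rolepred.model import ModelConfig, SRPModel, make_vocab, train_main
from rolepred.synth import generate_cdu_corpus, load_preset


def make_utterance(
    uid="u0", language="toy", tokens=("the", "fox", "hunts", "the", "chicken"),
    verb=(2, 3), verb_class="pursuit",
    args=(((0, 2), "A", "OTHER"), ((3, 5), "P", "OTHER")), conditions=None,
):
    return AnnotatedUtterance(
        id=uid,
        language=language,
        tokens=list(tokens),
        verb_span=verb,
        verb_class=verb_class,
        arguments=[ArgumentSpan(s, e, Role(r), Nominality(n)) for (s, e), r, n in args],
        conditions=conditions,
    )


@pytest.fixture
def fox_utterance():
    return make_utterance()


@pytest.fixture
def tiny_corpus():
    return Corpus(
        utterances=[
            make_utterance("u0"),
            make_utterance("u1", tokens=("she", "eats", "it"), verb=(1, 2), verb_class="ingestion",
                           args=(((0, 1), "A", "PRON_OTHER"), ((2, 3), "P", "PRON_OTHER"))),
            make_utterance("u2", tokens=("look", "here"), verb=(0, 1), verb_class="perception",
                           args=(((1, 2), "P", "OTHER"),)),
        ],
        metadata={"source": "fixture"},
    )


@pytest.fixture(scope="session")
def det_corpus():
    return generate_cdu_corpus(load_preset("deterministic_cue"), 600, seed=11)


@pytest.fixture(scope="session")
def trained_det_model(det_corpus):
    """Model trained on the deterministic-cue preset (shared across tests)."""
    utts = list(det_corpus)
    train, val = utts[:480], utts[480:540]
    config = ModelConfig(seed=11, max_epochs=6, patience=2)
    base = SRPModel(config, make_vocab([u.tokens for u in train + val]))
    fitted = train_main(base, train, val, config, from_scratch=True)
    return fitted, utts[540:]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
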