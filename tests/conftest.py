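import pytest

from medireader import difficulty, linker, ner, synth
from medireader.kb import Concept, KnowledgeBase, load_stopwords


@pytest.fixture(scope="session")
def toy_kb() -> KnowledgeBase:
    """Three concepts, five distinct alias strings, one deliberate ambiguity.

    "cold" is shared by the common-cold and the chronic-obstructive-disease
    concepts, mirroring the classic polysemy of clinical vocabulary.
    """
    return KnowledgeBase([
        Concept(id="C1", name="common cold", aliases=["cold"],
                definition="A viral infection with a runny nose and sneezing.",
                semtypes=["disorder"],
                relations=[("subclass_of", "C3")]),
        Concept(id="C2", name="chronic obstructive airway disease",
                aliases=["cold"],
                definition="A progressive airway obstruction with smoking "
                           "history and breathing difficulty.",
                semtypes=["disorder"],
                relations=[("subclass_of", "C3")]),
        Concept(id="C3", name="respiratory disorder", aliases=[],
                definition="Any disorder of breathing.",
                semtypes=["disorder"]),
    ], stopwords=load_stopwords())


@pytest.fixture(scope="session")
def synth_spec() -> synth.SynthSpec:
    return synth.SynthSpec(seed=7, n_concepts=20, n_sentences=30,
                           entity_density=0.3)


@pytest.fixture(scope="session")
def synth_kb(synth_spec):
    return synth.make_kb(synth_spec)


@pytest.fixture(scope="session")
def ner_corpus(synth_kb, synth_spec):
    sentences, gold = synth.make_ner_corpus(synth_kb, synth_spec)
    return sentences, gold


@pytest.fixture(scope="session")
def trained_tagger(ner_corpus):
    sentences, _ = ner_corpus
    return ner.train_tagger(sentences, ner.TaggerConfig(seed=3, epochs=200))


@pytest.fixture(scope="session")
def difficulty_dataset(synth_spec):
    return synth.make_difficulty_dataset(synth_spec)


@pytest.fixture(scope="session")
def trained_classifier(difficulty_dataset, synth_kb):
    pairs = [(term, label) for term, _, label in difficulty_dataset]
    return difficulty.DifficultyClassifier(kb=synth_kb).fit(pairs, seed=1)


@pytest.fixture(scope="session")
def kb_index(synth_kb):
    return linker.build_index(synth_kb)
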