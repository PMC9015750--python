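"""Synthetic fixtures for every pipeline stage — no downloads required.

Generators emulate the external resources a production deployment would
license: a concept vocabulary with controlled alias ambiguity (standing in
for UMLS/Wikidata), gold-tagged sentences whose entities are KB aliases
(standing in for an annotated clinical corpus), Bernoulli response matrices
drawn from the 3PL model (standing in for screening-test administrations),
and vote-labeled term-difficulty datasets produced by simulated 6-annotator
panels run through the real labeling rule.

Pseudo-terms are built from pronounceable syllables plus genuine medical
affixes, so surface-difficulty features vary realistically. Every generator
is a pure function of (spec, seed): repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .difficulty import load_affixes, load_lexicon, votes_to_label
from .irt import Item, ResponseMatrix, prob_correct
from .kb import Concept, KnowledgeBase, load_stopwords, normalize, write_kb
from .ner import TaggedSentence, write_conll

__all__ = ["IRTSpec", "DifficultySpec", "SynthSpec", "make_kb",
           "make_ner_corpus", "make_item_bank", "make_responses",
           "make_difficulty_dataset", "make_wsd_fixture"]

_CONSONANTS = "bdfglkmnprstvz"
_VOWELS = "aeiou"

# semantic type of a generated concept -> entity type used in tagging
SEMTYPE_TO_ENTITY = {"disorder": "Disease", "finding": "Problem",
                     "chemical": "Drug", "procedure": "Test"}

_FILLERS = ("the a was and with of noted on review today shows stable "
            "without for after prior improving unchanged since at during "
            "also remains this her his").split()


@dataclass(frozen=True)
class IRTSpec:
    n_items: int = 30
    n_persons: int = 2000
    a_range: tuple[float, float] = (0.8, 2.2)
    # difficulty skews low: the emulated screening instrument is built from
    # mostly easy questions so it can separate readers at the low end
    b_range: tuple[float, float] = (-2.0, 1.0)
    c_range: tuple[float, float] = (0.05, 0.25)


@dataclass(frozen=True)
class DifficultySpec:
    n_terms: int = 60
    proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # per-annotator probability of a positive (understood) vote by class
    vote_probs: tuple[float, float, float] = (0.99, 0.80, 0.25)


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    n_concepts: int = 50
    ambiguity_rate: float = 0.1
    n_sentences: int = 30
    entity_density: float = 0.3
    irt: IRTSpec = field(default_factory=IRTSpec)
    difficulty: DifficultySpec = field(default_factory=DifficultySpec)

    def __post_init__(self):
        if not (0 <= self.ambiguity_rate <= 1 and 0 <= self.entity_density <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.n_concepts, self.n_sentences) < 1:
            raise ValueError("counts must be positive")


def _syllable(rng) -> str:
    return rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))


def _pseudo_word(rng, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


class _SurfacePool:
    """Draws unique pseudo-term surfaces, never colliding with stop words."""

    def __init__(self, rng, stopwords: set[str]):
        self.rng = rng
        self.seen: set[str] = set(stopwords)
        pre, suf = load_affixes()
        self.prefixes, self.suffixes = pre, suf

    def draw(self, n_syllables: int = 3, affix_prob: float = 0.4) -> str:
        for _ in range(1000):
            w = _pseudo_word(self.rng, n_syllables)
            if self.rng.random() < affix_prob:
                if self.rng.random() < 0.5:
                    w = self.rng.choice(self.prefixes) + w
                else:
                    w = w + self.rng.choice(self.suffixes)
            if normalize(w) not in self.seen:
                self.seen.add(normalize(w))
                return w
        raise RuntimeError("surface pool exhausted")


def make_kb(spec: SynthSpec, path: str | Path | None = None) -> KnowledgeBase:
    """Generate a pseudo-medical KB with controlled alias ambiguity.

    Exactly ``round(ambiguity_rate * n_aliases)`` distinct alias strings are
    shared by two concepts (``n_aliases`` counts distinct non-canonical
    alias strings). Taxonomic relations form a forest; a few associative
    edges are added on top. Written as JSONL when ``path`` is given.
    """
    rng = np.random.default_rng(spec.seed)
    stopwords = load_stopwords()
    pool = _SurfacePool(rng, stopwords)
    semtypes = list(SEMTYPE_TO_ENTITY)
    concepts: list[Concept] = []
    for i in range(spec.n_concepts):
        st = semtypes[i % len(semtypes)]
        name = pool.draw(n_syllables=int(rng.integers(2, 5)))
        aliases = [pool.draw(n_syllables=int(rng.integers(2, 4)))
                   for _ in range(int(rng.integers(1, 5)))]
        topic = [_pseudo_word(rng, 2) for _ in range(2)]
        definition = (f"A {st} of the {_pseudo_word(rng, 2)} region "
                      f"characterized by {topic[0]} and {topic[1]}.")
        relations: list[tuple[str, str]] = []
        if i > 0 and rng.random() < 0.7:
            parent = concepts[int(rng.integers(0, i))]
            rtype = ["subclass_of", "instance_of", "part_of"][i % 3]
            relations.append((rtype, parent.id))
        concepts.append(Concept(id=f"S{i:04d}", name=name, aliases=aliases,
                                definition=definition, semtypes=[st],
                                relations=relations))
    # a few associative edges
    for i in range(0, spec.n_concepts - 1, 7):
        j = int(rng.integers(0, spec.n_concepts))
        if j != i:
            concepts[i].relations.append(
                ("associative:related_to", concepts[j].id))
    # inject exact alias sharing
    all_aliases = [(ci, a) for ci, c in enumerate(concepts) for a in c.aliases]
    n_shared = round(spec.ambiguity_rate * len(all_aliases))
    order = rng.permutation(len(all_aliases))
    shared = 0
    for idx in order:
        if shared >= n_shared:
            break
        ci, alias = all_aliases[int(idx)]
        cj = int(rng.integers(0, spec.n_concepts))
        if cj == ci:
            cj = (cj + 1) % spec.n_concepts
        if alias not in concepts[cj].aliases and alias != concepts[cj].name:
            concepts[cj].aliases.append(alias)
            shared += 1
    kb = KnowledgeBase(concepts, stopwords=stopwords)
    if path is not None:
        write_kb(kb, path)
    return kb


def entity_type_of(kb: KnowledgeBase, concept_id: str) -> str:
    st = kb.concepts[concept_id].semtypes
    return SEMTYPE_TO_ENTITY.get(st[0] if st else "", "Problem")


def make_ner_corpus(kb: KnowledgeBase, spec: SynthSpec,
                    conll_path: str | Path | None = None
                    ) -> tuple[list[TaggedSentence], list[dict]]:
    """Templated gold-tagged sentences whose entities are KB aliases.

    Per sentence the filler-token count is tied to the entity-token count so
    the overall entity density matches ``spec.entity_density`` closely.
    Returns the sentences and a gold mention table; optionally writes CoNLL.
    """
    if len(kb) == 0:
        raise ValueError("knowledge base is empty")
    rng = np.random.default_rng(spec.seed + 1)
    cids = sorted(kb.concepts)
    d = spec.entity_density
    sentences: list[TaggedSentence] = []
    gold: list[dict] = []
    for si in range(spec.n_sentences):
        n_ent = int(rng.integers(1, 3))
        ents = []
        for _ in range(n_ent):
            cid = cids[int(rng.integers(0, len(cids)))]
            c = kb.concepts[cid]
            surfaces = c.all_surfaces()
            surface = surfaces[int(rng.integers(0, len(surfaces)))]
            ents.append((cid, surface, entity_type_of(kb, cid)))
        e_tokens = sum(len(s.split()) for _, s, _ in ents)
        n_fill = max(1, round(e_tokens * (1 - d) / d)) if d > 0 else 10
        fillers = [str(rng.choice(_FILLERS)) for _ in range(n_fill)]
        # interleave: filler block, entity, filler block, entity, ..., rest
        cuts = sorted(rng.integers(0, n_fill + 1, size=n_ent))
        tokens: list[str] = []
        tags: list[str] = []
        prev = 0
        for (cid, surface, etype), cut in zip(ents, cuts):
            tokens.extend(fillers[prev:cut])
            tags.extend(["O"] * (cut - prev))
            parts = surface.split()
            start_tok = len(tokens)
            tokens.extend(parts)
            tags.extend([f"B-{etype}"] + [f"I-{etype}"] * (len(parts) - 1))
            gold.append({"sentence": si, "start_tok": start_tok,
                         "end_tok": start_tok + len(parts),
                         "surface": surface, "concept_candidates":
                         sorted(kb.lookup_alias(surface)), "type": etype})
            prev = cut
        tokens.extend(fillers[prev:])
        tags.extend(["O"] * (n_fill - prev))
        sentences.append(TaggedSentence(tokens, tags))
    if conll_path is not None:
        write_conll(sentences, conll_path)
    return sentences, gold


def make_item_bank(spec: SynthSpec) -> list[Item]:
    """Draw a 3PL item bank uniformly from the configured parameter ranges."""
    rng = np.random.default_rng(spec.seed + 2)
    irt = spec.irt
    items = []
    for i in range(irt.n_items):
        items.append(Item(
            id=f"Q{i + 1:02d}",
            a=float(rng.uniform(*irt.a_range)),
            b=float(rng.uniform(*irt.b_range)),
            c=float(rng.uniform(*irt.c_range))))
    return items


def make_responses(items: list[Item], n_persons: int,
                   seed: int) -> tuple[ResponseMatrix, np.ndarray]:
    """Simulate the 3PL response process: theta ~ N(0,1), entries Bernoulli.

    Returns the matrix and the true ability vector for recovery tests.
    """
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n_persons)
    P = np.column_stack([prob_correct(it, theta) for it in items])
    U = (rng.random(P.shape) < P).astype(float)
    matrix = ResponseMatrix(
        persons=[f"p{j:05d}" for j in range(n_persons)],
        items=[it.id for it in items], values=U)
    return matrix, theta


def make_difficulty_dataset(spec: SynthSpec
                            ) -> list[tuple[str, str, str]]:
    """Vote-labeled difficulty dataset: (term, intended class, panel label).

    Terms are class-separable by construction — easy terms are short common
    lexicon words, medium terms are bare pseudo-words, difficult terms are
    long pseudo-words carrying medical prefixes and suffixes. Labels come
    from 6 simulated Bernoulli annotator votes passed through the real
    vote-to-label rule, so the labeling procedure is exercised end to end.
    """
    rng = np.random.default_rng(spec.seed + 3)
    ds = spec.difficulty
    lexicon = sorted(w for w in load_lexicon() if w.isalpha() and len(w) <= 7)
    pool = _SurfacePool(rng, load_stopwords())
    n_by_class = [round(p * ds.n_terms) for p in ds.proportions]
    n_by_class[-1] = ds.n_terms - sum(n_by_class[:-1])
    used: set[str] = set()
    out: list[tuple[str, str, str]] = []
    for cls_idx, (cls, n_cls) in enumerate(zip(("easy", "medium", "difficult"),
                                               n_by_class)):
        p_vote = ds.vote_probs[cls_idx]
        for _ in range(n_cls):
            if cls == "easy":
                term = str(rng.choice([w for w in lexicon if w not in used]))
            elif cls == "medium":
                term = pool.draw(n_syllables=2, affix_prob=0.0)
            else:
                term = (str(rng.choice(pool.prefixes))
                        + _pseudo_word(rng, 3)
                        + str(rng.choice(pool.suffixes)))
                while normalize(term) in used:
                    term += _syllable(rng)
            used.add(normalize(term))
            votes = int((rng.random(6) < p_vote).sum())
            out.append((term, cls, votes_to_label(votes)))
    return out


def make_wsd_fixture(seed: int = 0, n_train: int = 5, n_test: int = 10
                     ) -> tuple[KnowledgeBase, str, list, list]:
    """An ambiguous surface with two senses of disjoint context vocabulary.

    Mirrors the classic polysemy problem (one surface, several concepts;
    e.g. a word meaning both an illness and a substance). Returns
    (kb, shared_surface, train_contexts, test_contexts) where contexts are
    (concept_id, sentence) pairs; train and test sentences are disjoint.
    """
    rng = np.random.default_rng(seed)
    surface = "kardol"
    vocab_a = [_pseudo_word(rng, 2) + "in" for _ in range(12)]
    vocab_b = [_pseudo_word(rng, 3) + "ax" for _ in range(12)]
    kb = KnowledgeBase([
        Concept(id="A1", name="kardol", aliases=["kardol disorder"],
                definition="A disorder involving " + " and ".join(vocab_a[:3]),
                semtypes=["disorder"]),
        Concept(id="B1", name="kardol", aliases=["kardol compound"],
                definition="A chemical compound containing "
                           + " and ".join(vocab_b[:3]),
                semtypes=["chemical"]),
    ], stopwords=load_stopwords())

    def sentence(vocab) -> str:
        words = [str(rng.choice(vocab)) for _ in range(3)]
        return f"{words[0]} {words[1]} {surface} {words[2]} noted"

    train = [("A1", sentence(vocab_a)) for _ in range(n_train)] + \
            [("B1", sentence(vocab_b)) for _ in range(n_train)]
    test = [("A1", sentence(vocab_a)) for _ in range(n_test)] + \
           [("B1", sentence(vocab_b)) for _ in range(n_test)]
    return kb, surface, train, test
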