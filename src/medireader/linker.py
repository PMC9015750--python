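"""Entity linking: candidate generation and context disambiguation.

Candidate generation encodes every (concept, alias) surface in the knowledge
base as a TF-IDF vector of character 3-grams (surfaces are boundary-padded
with ``#`` so aliases shorter than the n-gram length still produce n-grams;
n-grams occurring no more than ``min_count`` times in the KB are dropped).
A mention is encoded the same way and its k nearest concepts under cosine
similarity become the candidate set — an exact exhaustive search, which is
both the oracle and fast enough at desk scale.

Candidate ranking (word sense disambiguation) represents each candidate
sense by a context vector built from three feature families — unigrams,
salient bigrams, and positional collocations (offset, token) for offsets in
{-2, -1, +1, +2} — aggregated from the concept's KB definition and any
labeled training contexts, in a vector space model. The candidate whose
sense vector has maximal cosine with the mention's context vector wins;
with an empty or uninformative context the generation ranking stands.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .kb import KnowledgeBase, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "NGramIndex", "Candidate", "CandidateSet", "LinkedMention", "SenseModel",
    "build_index", "candidates", "rank_candidates", "char_ngrams",
]


def char_ngrams(surface: str, n: int = 3) -> list[str]:
    """Character n-grams of the normalized, ``#``-padded surface."""
    padded = "#" + normalize(surface) + "#"
    while len(padded) < n:
        padded += "#"
    return [padded[i:i + n] for i in range(len(padded) - n + 1)]


@dataclass
class Candidate:
    concept_id: str
    generation_score: float
    rank_score: float | None = None


@dataclass
class CandidateSet:
    mention: str
    candidates: list[Candidate]

    def ids(self) -> list[str]:
        return [c.concept_id for c in self.candidates]


@dataclass
class LinkedMention:
    surface: str
    concept_id: str
    score: float
    provenance: str   # "exact-alias" or "knn+wsd"


class NGramIndex:
    """TF-IDF character-n-gram index over all (concept, alias) surfaces.

    TF is the raw n-gram count in the alias; IDF = log((1+N)/(1+df)) + 1
    over the N alias strings; vectors are L2-normalized. Backed by
    scikit-learn's TfidfVectorizer with a custom padded-n-gram analyzer.
    """

    def __init__(self, kb: KnowledgeBase, n: int = 3, min_count: int = 1):
        if len(kb) == 0:
            raise ValueError("cannot index an empty knowledge base")
        self.n = n
        self.min_count = min_count
        self.kb = kb
        surfaces: list[str] = []
        self.row_concepts: list[str] = []
        self.row_surfaces: list[str] = []
        for cid in sorted(kb.concepts):
            for surface in kb.concepts[cid].all_surfaces():
                surfaces.append(surface)
                self.row_concepts.append(cid)
                self.row_surfaces.append(normalize(surface))
        counts = Counter(g for s in surfaces for g in set(char_ngrams(s, n)))
        # keep n-grams seen in >= min_count alias strings; the default of 1
        # keeps everything, so unique aliases never encode to zero vectors
        vocab = sorted(g for g, c in counts.items() if c >= min_count)
        if not vocab:
            raise ValueError(
                f"min_count={min_count} filters out every character "
                f"{n}-gram in the knowledge base")
        self._vectorizer = TfidfVectorizer(
            analyzer=lambda s: char_ngrams(s, self.n),
            vocabulary={g: i for i, g in enumerate(vocab)},
            norm="l2", smooth_idf=True, sublinear_tf=False)
        self.matrix = self._vectorizer.fit_transform(surfaces)

    @property
    def ngram_vocab(self) -> dict[str, int]:
        return dict(self._vectorizer.vocabulary_)

    @property
    def idf(self) -> np.ndarray:
        return self._vectorizer.idf_

    def encode(self, mention: str):
        """L2-normalized TF-IDF vector of a mention (may be all-zero)."""
        return self._vectorizer.transform([mention])

    def exact_alias_ids(self, mention: str) -> set[str]:
        return self.kb.lookup_alias(mention)


def build_index(kb: KnowledgeBase, n: int = 3, min_count: int = 1) -> NGramIndex:
    """Build the character-n-gram TF-IDF index for candidate generation."""
    return NGramIndex(kb, n=n, min_count=min_count)


def candidates(index: NGramIndex, mention: str, k: int = 25) -> CandidateSet:
    """Up to ``k`` distinct concepts ranked by cosine similarity to ``mention``.

    A mention with no in-vocabulary n-grams yields an empty candidate set
    (logged, not an error). Ties break by concept id for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vec = index.encode(mention)
    if vec.nnz == 0:
        logger.info("mention %r has no in-vocabulary %d-grams", mention, index.n)
        return CandidateSet(mention, [])
    sims = np.asarray((index.matrix @ vec.T).todense()).ravel()
    best: dict[str, float] = {}
    for row, sim in enumerate(sims):
        if sim <= 0:
            continue
        cid = index.row_concepts[row]
        if sim > best.get(cid, -1.0):
            best[cid] = float(sim)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return CandidateSet(mention, [Candidate(cid, s) for cid, s in ranked])


# ---------------------------------------------------------------------------
# Word sense disambiguation (vector space model over context features)
# ---------------------------------------------------------------------------

def _tokenize(text: str) -> list[str]:
    return [normalize(t) for t in text.split() if t.strip()]


def context_features(tokens: list[str], position: int | None = None,
                     window: int = 5) -> Counter:
    """Unigram + bigram + positional-collocation features of a context.

    ``position`` marks the mention's token index; collocations are emitted
    for offsets {-2, -1, +1, +2} relative to it. When the position is
    unknown (e.g. a KB definition used as a bag of words), only unigrams and
    bigrams are produced.
    """
    feats: Counter = Counter()
    if position is not None:
        lo = max(0, position - window)
        hi = min(len(tokens), position + window + 1)
        windowed = [(i, t) for i, t in enumerate(tokens)
                    if lo <= i < hi and i != position]
    else:
        windowed = list(enumerate(tokens))
    toks = [t for _, t in windowed]
    for t in toks:
        feats[f"u:{t}"] += 1
    for t1, t2 in zip(toks, toks[1:]):
        feats[f"b:{t1}_{t2}"] += 1
    if position is not None:
        for off in (-2, -1, 1, 2):
            j = position + off
            if 0 <= j < len(tokens):
                feats[f"c:{off}:{tokens[j]}"] += 1
    return feats


def _cosine(u: Counter, v: Counter) -> float:
    if not u or not v:
        return 0.0
    shared = set(u) & set(v)
    num = sum(u[f] * v[f] for f in shared)
    nu = np.sqrt(sum(x * x for x in u.values()))
    nv = np.sqrt(sum(x * x for x in v.values()))
    return float(num / (nu * nv)) if num else 0.0


class SenseModel:
    """Vector-space sense profiles per concept.

    Profiles aggregate features from KB definitions (always available) and
    optional labeled training contexts (JSONL: surface, concept, context).
    """

    def __init__(self, kb: KnowledgeBase, window: int = 5):
        self.kb = kb
        self.window = window
        self.profiles: dict[str, Counter] = {}
        for cid, concept in kb.concepts.items():
            feats: Counter = Counter()
            if concept.definition:
                feats += context_features(_tokenize(concept.definition))
            self.profiles[cid] = feats

    def add_context(self, concept_id: str, context: str,
                    surface: str | None = None) -> None:
        tokens = _tokenize(context)
        position = None
        if surface is not None:
            surf = normalize(surface)
            for i, t in enumerate(tokens):
                if t == surf:
                    position = i
                    break
        self.profiles.setdefault(concept_id, Counter())
        self.profiles[concept_id] += context_features(tokens, position,
                                                      self.window)

    @classmethod
    def from_training_file(cls, kb: KnowledgeBase, path: str | Path,
                           window: int = 5) -> "SenseModel":
        model = cls(kb, window=window)
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            model.add_context(rec["concept"], rec["context"],
                              rec.get("surface"))
        return model

    def score(self, concept_id: str, context_vec: Counter) -> float:
        return _cosine(self.profiles.get(concept_id, Counter()), context_vec)


def rank_candidates(cands: CandidateSet, context: list[str] | str,
                    sense_model: SenseModel,
                    mention_position: int | None = None) -> LinkedMention:
    """Resolve a candidate set against its context via the sense model.

    A single candidate is returned unchanged; with several, the one whose
    sense profile is most cosine-similar to the mention's context features
    wins. An empty or uninformative context (all sense scores zero) falls
    back to the generation order.
    """
    if not cands.candidates:
        raise ValueError("cannot rank an empty candidate set")
    if len(cands.candidates) == 1:
        c = cands.candidates[0]
        return LinkedMention(cands.mention, c.concept_id,
                             c.generation_score, "knn+wsd")
    tokens = _tokenize(context) if isinstance(context, str) else \
        [normalize(t) for t in context]
    ctx_vec = context_features(tokens, mention_position, sense_model.window) \
        if tokens else Counter()
    scored = []
    for c in cands.candidates:
        c.rank_score = sense_model.score(c.concept_id, ctx_vec)
        scored.append(c)
    best = max(scored, key=lambda c: c.rank_score)
    if best.rank_score <= 0.0:      # uninformative context: keep generation order
        top = cands.candidates[0]
        return LinkedMention(cands.mention, top.concept_id,
                             top.generation_score, "knn+wsd")
    return LinkedMention(cands.mention, best.concept_id, best.rank_score,
                         "knn+wsd")
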