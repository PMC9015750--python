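"""Lexical difficulty of medical terms: features, gold labels, classifiers.

A term is labeled easy / medium / difficult. Gold labels derive from a
6-annotator comprehension panel: 6 positive votes -> easy, 5 or 4 -> medium,
fewer than 4 -> difficult (:func:`votes_to_label`).

Prediction uses a feature set mixing surface statistics (character and
syllable counts, consonant/vowel percentages, medical prefixes and
suffixes), lexicon presence, corpus frequencies (general and medical) and
semantic types, optionally concatenated with a learned character-level
encoding of the term (char-CNN + BiLSTM), mirroring the neural tagger's
encoder. A plain logistic-regression model over the dense features alone is
available as a lightweight fallback.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from ._autograd import Adam, Tensor, concatenate
from .kb import KnowledgeBase, normalize

__all__ = [
    "LABELS", "TermFeatures", "Resources", "count_syllables",
    "extract_features", "votes_to_label", "DifficultyClassifier",
    "train_difficulty_classifier", "build_medical_freq",
]

LABELS = ("easy", "medium", "difficult")

VOWELS = set("aeiou")
SYLLABLE_VOWELS = set("aeiouy")

SYNTACTIC_CATEGORIES = ("noun", "verb", "adjective", "adverb",
                        "abbreviation", "other")
SEMTYPE_INVENTORY = ("disorder", "procedure", "chemical", "anatomy",
                     "finding", "device", "organism", "other")

_ADJ_SUFFIXES = ("ic", "al", "ous", "ary", "ive", "able")
_ADV_SUFFIXES = ("ly",)
_VERB_SUFFIXES = ("ize", "ise", "ate")


def count_syllables(word: str) -> int:
    """Syllables as maximal vowel groups (aeiouy), with a silent-e rule.

    A trailing ``e`` preceded by a consonant does not count as its own
    syllable when the word has more than one vowel group; every word with a
    vowel has at least one syllable.
    """
    if not word:
        raise ValueError("word must be non-empty")
    w = word.lower()
    groups = re.findall(r"[aeiouy]+", w)
    n = len(groups)
    if (n > 1 and w.endswith("e") and len(w) >= 2
            and w[-2] not in SYLLABLE_VOWELS and groups[-1] == "e"):
        n -= 1
    return max(n, 1)


def load_affixes(path: str | Path | None = None) -> tuple[list[str], list[str]]:
    """Load the medical prefix/suffix inventories (resource file by default)."""
    if path is None:
        text = _ilres.files("medireader.resources").joinpath(
            "affixes.txt").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    prefixes, suffixes = [], []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        kind, _, affix = line.partition(":")
        (prefixes if kind == "prefix" else suffixes).append(affix)
    return prefixes, suffixes


def load_frequency_table(path: str | Path | None = None) -> dict[str, float]:
    """Load a term TAB count frequency table (general-English by default)."""
    if path is None:
        text = _ilres.files("medireader.resources").joinpath(
            "freq_general.tsv").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, _, count = line.rpartition("\t")
        table[normalize(term)] = float(count)
    return table


def load_lexicon(path: str | Path | None = None) -> set[str]:
    """Load the general-language lexicon (one word per line)."""
    if path is None:
        text = _ilres.files("medireader.resources").joinpath(
            "lexicon_en.txt").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return {normalize(w) for w in text.splitlines()
            if w.strip() and not w.startswith("#")}


def build_medical_freq(kb: KnowledgeBase) -> dict[str, float]:
    """Medical frequency table: how often each token occurs across KB surfaces."""
    freq: dict[str, float] = {}
    for concept in kb.concepts.values():
        for surface in concept.all_surfaces():
            for tok in normalize(surface).split():
                freq[tok] = freq.get(tok, 0.0) + 1.0
    return freq


@dataclass
class Resources:
    """Pluggable lookups behind the irreproducible external services."""

    freq_general: dict[str, float] = field(default_factory=load_frequency_table)
    freq_medical: dict[str, float] = field(default_factory=dict)
    lexicon: set[str] = field(default_factory=load_lexicon)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    embedding_dim: int = 16
    prefixes: list[str] = None
    suffixes: list[str] = None

    def __post_init__(self):
        if self.prefixes is None or self.suffixes is None:
            pre, suf = load_affixes()
            self.prefixes = pre if self.prefixes is None else self.prefixes
            self.suffixes = suf if self.suffixes is None else self.suffixes


@dataclass
class TermFeatures:
    term: str
    syntactic_category: str
    n_chars: int
    n_syllables: int
    prefix: str | None
    suffix: str | None
    n_consonants: int
    n_vowels: int
    n_other: int
    pct_consonants: float
    pct_vowels: float
    pct_other: float
    in_wordnet: bool
    freq_general: float
    freq_medical: float
    semtypes: list[str]
    embedding: np.ndarray

    def vector(self, resources: Resources) -> np.ndarray:
        """Fixed-dimension dense encoding of the features.

        Layout: 5 counts, 3 percentages (0-1), lexicon flag, 2 log
        frequencies, syntactic one-hot, prefix one-hot (+none), suffix
        one-hot (+none), semtype multi-hot, embedding. Dimension is a
        function of the resource inventories only.
        """
        syn = np.zeros(len(SYNTACTIC_CATEGORIES))
        syn[SYNTACTIC_CATEGORIES.index(self.syntactic_category)] = 1.0
        pre = np.zeros(len(resources.prefixes) + 1)
        pre[resources.prefixes.index(self.prefix) if self.prefix else -1] = 1.0
        suf = np.zeros(len(resources.suffixes) + 1)
        suf[resources.suffixes.index(self.suffix) if self.suffix else -1] = 1.0
        sem = np.zeros(len(SEMTYPE_INVENTORY))
        for st in self.semtypes:
            key = st if st in SEMTYPE_INVENTORY else "other"
            sem[SEMTYPE_INVENTORY.index(key)] = 1.0
        return np.concatenate([
            [self.n_chars, self.n_syllables, self.n_consonants,
             self.n_vowels, self.n_other],
            [self.pct_consonants / 100, self.pct_vowels / 100,
             self.pct_other / 100],
            [float(self.in_wordnet)],
            [math.log1p(self.freq_general), math.log1p(self.freq_medical)],
            syn, pre, suf, sem, self.embedding,
        ])

    @staticmethod
    def dim(resources: Resources) -> int:
        return (5 + 3 + 1 + 2 + len(SYNTACTIC_CATEGORIES)
                + len(resources.prefixes) + 1 + len(resources.suffixes) + 1
                + len(SEMTYPE_INVENTORY) + resources.embedding_dim)


def _syntactic_category(term: str) -> str:
    w = term.strip()
    if not any(ch.isalpha() for ch in w):
        return "other"
    if w.isupper() and 2 <= len(w) <= 6:
        return "abbreviation"
    lw = w.lower()
    if lw.endswith(_ADV_SUFFIXES):
        return "adverb"
    if lw.endswith(_ADJ_SUFFIXES):
        return "adjective"
    if lw.endswith(_VERB_SUFFIXES):
        return "verb"
    return "noun"   # isolated medical terms default to nouns


def extract_features(term: str, kb: KnowledgeBase | None = None,
                     resources: Resources | None = None) -> TermFeatures:
    """Deterministic feature extraction for one term.

    Missing lookups take neutral values: frequency 0, lexicon flag false,
    zero embedding. Multi-word terms count spaces (and other non-letters)
    as "other" characters.
    """
    if not term:
        raise ValueError("term must be non-empty")
    resources = resources or Resources()
    lw = normalize(term)
    n_chars = len(term)
    n_vowels = sum(1 for ch in term.lower() if ch in VOWELS)
    n_consonants = sum(1 for ch in term.lower()
                       if ch.isalpha() and ch not in VOWELS)
    n_other = n_chars - n_vowels - n_consonants
    pct = (lambda x: 100.0 * x / n_chars)
    prefix = next((p for p in sorted(resources.prefixes, key=len, reverse=True)
                   if lw.startswith(p)), None)
    suffix = next((s for s in sorted(resources.suffixes, key=len, reverse=True)
                   if lw.endswith(s)), None)
    semtypes: list[str] = []
    freq_medical = resources.freq_medical.get(lw, 0.0)
    if kb is not None:
        ids = kb.lookup_alias(term)
        for cid in sorted(ids):
            semtypes.extend(kb.concepts[cid].semtypes)
        if not resources.freq_medical:
            freq_medical = float(len(ids))
    emb = resources.embeddings.get(
        lw, np.zeros(resources.embedding_dim))
    syllable_word = lw.replace(" ", "")
    return TermFeatures(
        term=term,
        syntactic_category=_syntactic_category(term),
        n_chars=n_chars,
        n_syllables=count_syllables(syllable_word) if syllable_word else 1,
        prefix=prefix,
        suffix=suffix,
        n_consonants=n_consonants,
        n_vowels=n_vowels,
        n_other=n_other,
        pct_consonants=pct(n_consonants),
        pct_vowels=pct(n_vowels),
        pct_other=pct(n_other),
        in_wordnet=lw in resources.lexicon,
        freq_general=resources.freq_general.get(lw, 0.0),
        freq_medical=freq_medical,
        semtypes=sorted(set(semtypes)),
        embedding=np.asarray(emb, dtype=float),
    )


def votes_to_label(positive_votes: int, panel_size: int = 6) -> str:
    """Map a 6-annotator comprehension vote to a difficulty label.

    All positive votes -> easy; one or two dissenters -> medium; fewer than
    4 positive votes -> difficult.
    """
    if not (0 <= positive_votes <= panel_size):
        raise ValueError(
            f"votes must lie in [0, {panel_size}], got {positive_votes}")
    if positive_votes == panel_size:
        return "easy"
    if positive_votes >= panel_size - 2:
        return "medium"
    return "difficult"


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    char_dim: int = 12
    n_filters: int = 16
    hidden: int = 16
    lr: float = 0.02
    epochs: int = 150
    seed: int = 0
    backend: str = "neural"    # "neural" or "logistic"


class DifficultyClassifier:
    """Easy/medium/difficult classifier over term strings + dense features.

    The default backend combines a character-level encoder (width-3 CNN with
    max-over-time pooling plus a BiLSTM over character embeddings) with the
    :class:`TermFeatures` vector, concatenated before a softmax output
    layer. The "logistic" backend is scikit-learn logistic regression over
    the dense features alone.
    """

    def __init__(self, config: ClassifierConfig | None = None,
                 kb: KnowledgeBase | None = None,
                 resources: Resources | None = None):
        self.config = config or ClassifierConfig()
        self.kb = kb
        self.resources = resources or Resources()
        self.params: dict[str, Tensor] | None = None
        self.char_vocab: dict[str, int] | None = None
        self._sk_model: LogisticRegression | None = None
        self._feat_mean: np.ndarray | None = None
        self._feat_scale: np.ndarray | None = None

    # -- features ----------------------------------------------------------------

    def _features(self, term: str) -> np.ndarray:
        return extract_features(term, self.kb, self.resources).vector(
            self.resources)

    def _scaled(self, term: str) -> np.ndarray:
        x = self._features(term)
        return (x - self._feat_mean) / self._feat_scale

    def _char_ids(self, term: str) -> list[int]:
        cv = self.char_vocab
        ids = [cv.get(ch, cv["<unk>"]) for ch in normalize(term)]
        return ids or [cv["<pad>"]]

    def _encode(self, term: str) -> Tensor:
        p = self.params
        H = self.config.hidden
        cids = [self.char_vocab["<pad>"]] + self._char_ids(term) \
            + [self.char_vocab["<pad>"]]
        E = p["char_emb"][np.array(cids)]
        windows = concatenate([E[:-2], E[1:-1], E[2:]], axis=1)
        conv = (windows @ p["conv_w"] + p["conv_b"]).tanh()
        pooled = conv.max(axis=0)

        def lstm(seq_idx, prefix):
            h = Tensor(np.zeros(H))
            c = Tensor(np.zeros(H))
            for i in seq_idx:
                x = E[i]
                z = x @ p[f"{prefix}_wx"] + h @ p[f"{prefix}_wh"] + p[f"{prefix}_b"]
                ii = z[0:H].sigmoid()
                f = z[H:2 * H].sigmoid()
                g = z[2 * H:3 * H].tanh()
                o = z[3 * H:4 * H].sigmoid()
                c = f * c + ii * g
                h = o * c.tanh()
            return h

        n = len(cids)
        fwd = lstm(range(n), "fw")
        bwd = lstm(range(n - 1, -1, -1), "bw")
        feats = Tensor(self._scaled(term))
        joint = concatenate([pooled, fwd, bwd, feats], axis=0)
        hidden = (joint @ p["h_w"] + p["h_b"]).tanh()
        return hidden @ p["out_w"] + p["out_b"]

    # -- training -------------------------------------------------------------------

    def fit(self, dataset: list[tuple[str, str]],
            seed: int | None = None) -> "DifficultyClassifier":
        """Fit on (term, label) pairs; labels must cover >= 2 classes."""
        labels = {lab for _, lab in dataset}
        if not labels <= set(LABELS):
            raise ValueError(f"unknown labels: {labels - set(LABELS)}")
        if len(labels) < 2:
            raise ValueError("dataset must cover at least 2 classes")
        cfg = self.config
        if seed is not None:
            cfg.seed = seed
        X = np.array([self._features(t) for t, _ in dataset])
        self._feat_mean = X.mean(axis=0)
        self._feat_scale = X.std(axis=0)
        self._feat_scale[self._feat_scale < 1e-9] = 1.0

        if cfg.backend == "logistic":
            y = [LABELS.index(lab) for _, lab in dataset]
            self._sk_model = LogisticRegression(
                max_iter=2000, random_state=cfg.seed)
            self._sk_model.fit((X - self._feat_mean) / self._feat_scale, y)
            return self

        rng = np.random.default_rng(cfg.seed)
        chars = sorted({ch for t, _ in dataset for ch in normalize(t)})
        self.char_vocab = {"<pad>": 0, "<unk>": 1,
                           **{c: i + 2 for i, c in enumerate(chars)}}
        Dc, F, H = cfg.char_dim, cfg.n_filters, cfg.hidden
        fdim = TermFeatures.dim(self.resources)
        joint_dim = F + 2 * H + fdim

        def init(*shape):
            return Tensor(rng.normal(0, 1.0 / math.sqrt(shape[0]), size=shape),
                          requires_grad=True)

        self.params = {
            "char_emb": init(len(self.char_vocab), Dc),
            "conv_w": init(3 * Dc, F),
            "conv_b": Tensor(np.zeros(F), requires_grad=True),
            "fw_wx": init(Dc, 4 * H), "fw_wh": init(H, 4 * H),
            "fw_b": Tensor(np.zeros(4 * H), requires_grad=True),
            "bw_wx": init(Dc, 4 * H), "bw_wh": init(H, 4 * H),
            "bw_b": Tensor(np.zeros(4 * H), requires_grad=True),
            "h_w": init(joint_dim, H),
            "h_b": Tensor(np.zeros(H), requires_grad=True),
            "out_w": init(H, len(LABELS)),
            "out_b": Tensor(np.zeros(len(LABELS)), requires_grad=True),
        }
        opt = Adam(list(self.params.values()), lr=cfg.lr)
        order = np.arange(len(dataset))
        self.loss_history: list[float] = []
        for _epoch in range(cfg.epochs):
            rng.shuffle(order)
            total = 0.0
            for i in order:
                term, lab = dataset[i]
                logits = self._encode(term)
                y = LABELS.index(lab)
                loss = logits.logsumexp(axis=0) - logits[y]
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += loss.item()
            self.loss_history.append(total / len(dataset))
            if self.loss_history[-1] < 1e-3:
                break
        return self

    def predict(self, term: str) -> str:
        if self._sk_model is not None:
            x = self._scaled(term)
            return LABELS[int(self._sk_model.predict(x[None, :])[0])]
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        logits = self._encode(term).data
        return LABELS[int(np.argmax(logits))]

    def accuracy(self, dataset: list[tuple[str, str]]) -> float:
        hits = sum(self.predict(t) == lab for t, lab in dataset)
        return hits / len(dataset)


def train_difficulty_classifier(dataset, config: ClassifierConfig | None = None,
                                seed: int = 0,
                                kb: KnowledgeBase | None = None,
                                resources: Resources | None = None
                                ) -> DifficultyClassifier:
    """Train a difficulty classifier on (term, label) or (term, context, label).

    Contexts are accepted for interface compatibility but the classifier
    conditions on the term surface and its dense features.
    """
    pairs = [(rec[0], rec[-1]) for rec in dataset]
    clf = DifficultyClassifier(config, kb=kb, resources=resources)
    return clf.fit(pairs, seed=seed)
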