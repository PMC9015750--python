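"""Medical named entity recognition with a BiLSTM-CNN-CRF tagger.

Each token is encoded by the concatenation of a word embedding and a
character-level representation computed by a width-3 convolution over
character embeddings with max-over-time pooling. A bidirectional LSTM reads
the token encodings forward and backward; the concatenated hidden states are
projected to per-tag emission scores, and a linear-chain CRF with explicit
start/stop transitions jointly decodes the best tag sequence for the whole
sentence (Viterbi) and normalizes the training likelihood (forward
algorithm).

Tags follow the BIO scheme over the entity types {Disease, Problem, Drug,
Test}. Constrained decoding (invalid BIO transitions forced to -inf) is on
by default.

The numerical core runs on the package's own reverse-mode autodiff engine
(:mod:`medireader._autograd`); public CRF functions below are plain numpy.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor, concatenate

__all__ = [
    "Mention", "TaggedSentence", "TaggerConfig", "TaggerModel",
    "tokenize_with_offsets", "read_conll", "write_conll",
    "crf_log_partition", "crf_viterbi", "train_tagger", "tag",
    "tags_to_spans", "entity_f1", "load_word_vectors",
]

ENTITY_TYPES = ("Disease", "Problem", "Drug", "Test")

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Rule-based tokenizer: word characters or single punctuation marks.

    Returns (token, start, end) with 0-based half-open offsets into ``text``.
    """
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _check_bio(tags: list[str]) -> None:
    prev = "O"
    for t in tags:
        if t == "O":
            prev = t
            continue
        if "-" not in t:
            raise ValueError(f"malformed tag {t!r}")
        head, etype = t.split("-", 1)
        if head not in ("B", "I"):
            raise ValueError(f"malformed tag {t!r}")
        if head == "I":
            if prev == "O" or prev.split("-", 1)[1] != etype:
                raise ValueError(f"invalid BIO sequence: {t!r} after {prev!r}")
        prev = t


@dataclass
class Mention:
    """A recognized entity span with type and character offsets."""

    surface: str
    type: str
    start: int
    end: int


@dataclass
class TaggedSentence:
    tokens: list[str]
    tags: list[str]
    char_offsets: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must have equal length")
        if self.char_offsets is not None and len(self.char_offsets) != len(self.tokens):
            raise ValueError("char_offsets must align with tokens")
        _check_bio(self.tags)


def read_conll(path: str | Path) -> list[TaggedSentence]:
    """Read a two-column (token TAB tag) corpus, blank line between sentences."""
    sentences = []
    tokens: list[str] = []
    tags: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            if tokens:
                sentences.append(TaggedSentence(tokens, tags))
                tokens, tags = [], []
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed CoNLL line: {line!r}")
        tokens.append(parts[0])
        tags.append(parts[1])
    if tokens:
        sentences.append(TaggedSentence(tokens, tags))
    return sentences


def write_conll(sentences: list[TaggedSentence], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for sent in sentences:
            for tok, t in zip(sent.tokens, sent.tags):
                fh.write(f"{tok}\t{t}\n")
            fh.write("\n")


def tags_to_spans(tags: list[str]) -> list[tuple[str, int, int]]:
    """BIO tags -> (entity_type, first_token, last_token+1) spans."""
    spans = []
    start, etype = None, None
    for i, t in enumerate(tags + ["O"]):
        head = t.split("-", 1)[0]
        ttype = t.split("-", 1)[1] if "-" in t else None
        if start is not None and (head in ("O", "B") or ttype != etype):
            spans.append((etype, start, i))
            start, etype = None, None
        if head == "B":
            start, etype = i, ttype
        elif head == "I" and start is None:   # tolerate stray I- at decode time
            start, etype = i, ttype
    return spans


def entity_f1(gold: list[list[str]], pred: list[list[str]]) -> float:
    """Exact-span entity F1 between gold and predicted tag sequences."""
    tp = fp = fn = 0
    for si, (g, p) in enumerate(zip(gold, pred)):
        gspans = {(si, *s) for s in tags_to_spans(g)}
        pspans = {(si, *s) for s in tags_to_spans(p)}
        tp += len(gspans & pspans)
        fp += len(pspans - gspans)
        fn += len(gspans - pspans)
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


# ---------------------------------------------------------------------------
# Linear-chain CRF (plain numpy; start index T, stop index T+1)
# ---------------------------------------------------------------------------

def _validate_crf(emissions: np.ndarray, transitions: np.ndarray) -> tuple[int, int]:
    emissions = np.asarray(emissions, float)
    transitions = np.asarray(transitions, float)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be an L x T matrix with L >= 1")
    L, T = emissions.shape
    if transitions.shape != (T + 2, T + 2):
        raise ValueError(f"transitions must be {(T + 2, T + 2)}")
    if not np.isfinite(emissions).all():
        raise ValueError("emission scores must be finite")
    if np.isnan(transitions).any() or np.isposinf(transitions).any():
        raise ValueError("transition scores must be finite or -inf")
    return L, T


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all T^L tag paths of exp(path score), forward recursion.

    Path score = transitions[start, y_0] + sum_t emissions[t, y_t]
               + sum_t transitions[y_{t-1}, y_t] + transitions[y_{L-1}, stop].
    """
    emissions = np.asarray(emissions, float)
    transitions = np.asarray(transitions, float)
    L, T = _validate_crf(emissions, transitions)
    start, stop = T, T + 1
    alpha = transitions[start, :T] + emissions[0]
    for t in range(1, L):
        scores = alpha[:, None] + transitions[:T, :T] + emissions[t][None, :]
        m = scores.max(axis=0)
        alpha = m + np.log(np.exp(scores - m[None, :]).sum(axis=0))
    final = alpha + transitions[:T, stop]
    m = final.max()
    return float(m + np.log(np.exp(final - m).sum()))


def crf_viterbi(emissions: np.ndarray,
                transitions: np.ndarray) -> tuple[list[int], float]:
    """Best-scoring tag path and its score (max-product forward recursion).

    Ties resolve to the first (lowest-index) argmax at every step, so a fully
    tied instance returns the lexicographically smallest tag-index path.
    """
    emissions = np.asarray(emissions, float)
    transitions = np.asarray(transitions, float)
    L, T = _validate_crf(emissions, transitions)
    start, stop = T, T + 1
    delta = transitions[start, :T] + emissions[0]
    back = np.zeros((L, T), dtype=int)
    for t in range(1, L):
        scores = delta[:, None] + transitions[:T, :T] + emissions[t][None, :]
        back[t] = scores.argmax(axis=0)
        delta = scores[back[t], np.arange(T)]
    final = delta + transitions[:T, stop]
    last = int(final.argmax())
    best_score = float(final[last])
    path = [last]
    for t in range(L - 1, 0, -1):
        last = int(back[t, last])
        path.append(last)
    return path[::-1], best_score


# ---------------------------------------------------------------------------
# Tagger model
# ---------------------------------------------------------------------------

UNK, PAD = "<unk>", "<pad>"


@dataclass
class TaggerConfig:
    word_dim: int = 32
    char_dim: int = 16
    n_filters: int = 24
    hidden: int = 32
    lr: float = 0.02
    epochs: int = 200
    seed: int = 0
    constrained_decoding: bool = True
    stop_at_zero_loss: float = 1e-3   # early stop when mean sentence loss is below


def _bio_tagset(entity_types=ENTITY_TYPES) -> list[str]:
    tags = ["O"]
    for et in entity_types:
        tags += [f"B-{et}", f"I-{et}"]
    return tags


def _bio_mask(tags: list[str]) -> np.ndarray:
    """(T+2)x(T+2) additive mask: 0 for legal BIO transitions, -inf otherwise."""
    T = len(tags)
    mask = np.zeros((T + 2, T + 2))

    def legal(prev: str | None, nxt: str | None) -> bool:
        if nxt is None:        # -> stop, always fine
            return True
        if nxt == "O" or nxt.startswith("B-"):
            return True
        etype = nxt.split("-", 1)[1]
        return prev is not None and prev != "O" and prev.split("-", 1)[1] == etype

    for i, prev in enumerate(tags):
        for j, nxt in enumerate(tags):
            if not legal(prev, nxt):
                mask[i, j] = -np.inf
    for j, nxt in enumerate(tags):     # from start
        if not legal(None, nxt):
            mask[T, j] = -np.inf
    mask[:, T] = -np.inf               # nothing enters start
    mask[T + 1, :] = -np.inf           # nothing leaves stop
    return mask


class TaggerModel:
    """Trained BiLSTM-CNN-CRF tagger with vocabularies and parameters."""

    def __init__(self, word_vocab: dict[str, int], char_vocab: dict[str, int],
                 tags: list[str], config: TaggerConfig,
                 params: dict[str, Tensor]):
        self.word_vocab = word_vocab
        self.char_vocab = char_vocab
        self.tags = tags
        self.config = config
        self.params = params
        self._mask = _bio_mask(tags)

    # -- encoding --------------------------------------------------------------

    def _word_ids(self, tokens: list[str]) -> list[int]:
        wv = self.word_vocab
        return [wv.get(t.lower(), wv[UNK]) for t in tokens]

    def _char_ids(self, token: str) -> list[int]:
        cv = self.char_vocab
        ids = [cv.get(ch, cv[UNK]) for ch in token]
        return ids or [cv[PAD]]

    def _emissions(self, tokens: list[str]) -> Tensor:
        """L x T emission scores via char-CNN + word embedding -> BiLSTM."""
        p = self.params
        H = self.config.hidden
        inputs = []
        for tok, wid in zip(tokens, self._word_ids(tokens)):
            wemb = p["word_emb"][wid]
            cids = [self.char_vocab[PAD]] + self._char_ids(tok) + [self.char_vocab[PAD]]
            E = p["char_emb"][np.array(cids)]
            windows = concatenate([E[:-2], E[1:-1], E[2:]], axis=1)
            conv = (windows @ p["conv_w"] + p["conv_b"]).tanh()
            cfeat = conv.max(axis=0)
            inputs.append(concatenate([wemb, cfeat], axis=0))

        def lstm_run(seq, prefix):
            h = Tensor(np.zeros(H))
            c = Tensor(np.zeros(H))
            outs = []
            for x in seq:
                z = x @ p[f"{prefix}_wx"] + h @ p[f"{prefix}_wh"] + p[f"{prefix}_b"]
                i = z[0:H].sigmoid()
                f = z[H:2 * H].sigmoid()
                g = z[2 * H:3 * H].tanh()
                o = z[3 * H:4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outs.append(h)
            return outs

        fwd = lstm_run(inputs, "fw")
        bwd = lstm_run(inputs[::-1], "bw")[::-1]
        rows = [concatenate([f, b], axis=0).reshape(1, 2 * H)
                for f, b in zip(fwd, bwd)]
        hs = concatenate(rows, axis=0)
        return hs @ p["proj_w"] + p["proj_b"]

    def _transitions(self, constrained: bool) -> np.ndarray:
        trans = self.params["trans"].data.copy()
        if constrained:
            trans = trans + self._mask
        return trans

    # -- training loss -----------------------------------------------------------

    def _sentence_loss(self, sent: TaggedSentence) -> Tensor:
        """Negative CRF log-likelihood: logZ minus the gold path score."""
        em = self._emissions(sent.tokens)
        trans = self.params["trans"]
        T = len(self.tags)
        L = len(sent.tokens)
        y = [self.tags.index(t) for t in sent.tags]
        # gold path score
        gold = em[(np.arange(L), np.array(y))].sum()
        rows = np.array([T] + y)
        cols = np.array(y + [T + 1])
        gold = gold + trans[(rows, cols)].sum()
        # forward recursion in autograd
        alpha = trans[T, 0:T] + em[0]
        for t in range(1, L):
            scores = alpha.reshape(T, 1) + trans[0:T, 0:T] + em[t].reshape(1, T)
            alpha = scores.logsumexp(axis=0)
        logz = (alpha + trans[0:T, T + 1]).logsumexp(axis=0)
        return logz - gold

    # -- inference -----------------------------------------------------------------

    def predict_tags(self, tokens: list[str]) -> list[str]:
        if not tokens:
            return []
        em = self._emissions(tokens).data
        trans = self._transitions(self.config.constrained_decoding)
        path, _ = crf_viterbi(em, trans)
        return [self.tags[i] for i in path]

    def tag_text(self, text: str) -> list[Mention]:
        toks = tokenize_with_offsets(text)
        if not toks:
            return []
        tokens = [t for t, _, _ in toks]
        tags = self.predict_tags(tokens)
        mentions = []
        for etype, i, j in tags_to_spans(tags):
            start = toks[i][1]
            end = toks[j - 1][2]
            mentions.append(Mention(text[start:end], etype, start, end))
        return mentions

    # -- serialization ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        obj = {
            "word_vocab": self.word_vocab,
            "char_vocab": self.char_vocab,
            "tags": self.tags,
            "config": vars(self.config),
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(obj), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        cfg = TaggerConfig(**obj["config"])
        params = {k: Tensor(np.array(v), requires_grad=True)
                  for k, v in obj["params"].items()}
        return cls(obj["word_vocab"], obj["char_vocab"], obj["tags"], cfg, params)


def load_word_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read pretrained embeddings in the standard text format: word v1 v2 ..."""
    vecs = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.rstrip().split(" ")
        if len(parts) < 2:
            continue
        vecs[parts[0]] = np.array([float(x) for x in parts[1:]])
    return vecs


def train_tagger(corpus: list[TaggedSentence], config: TaggerConfig | None = None,
                 seed: int | None = None,
                 pretrained: dict[str, np.ndarray] | None = None) -> TaggerModel:
    """Train the tagger by minimizing the negative CRF log-likelihood.

    Deterministic given (corpus, config, seed): parameter initialization and
    the per-epoch sentence order derive from one seeded generator.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    cfg = config or TaggerConfig()
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng(cfg.seed)

    tags = _bio_tagset()
    for sent in corpus:
        for t in sent.tags:
            if t not in tags:
                raise ValueError(f"tag {t!r} outside the declared tag set")

    words = sorted({tok.lower() for s in corpus for tok in s.tokens})
    chars = sorted({ch for s in corpus for tok in s.tokens for ch in tok})
    word_vocab = {UNK: 0, **{w: i + 1 for i, w in enumerate(words)}}
    char_vocab = {PAD: 0, UNK: 1, **{c: i + 2 for i, c in enumerate(chars)}}

    D, Dc, F, H = cfg.word_dim, cfg.char_dim, cfg.n_filters, cfg.hidden
    Din = D + F
    T = len(tags)

    def init(*shape, scale=None):
        scale = scale or 1.0 / math.sqrt(shape[0])
        return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

    params = {
        "word_emb": init(len(word_vocab), D, scale=0.5),
        "char_emb": init(len(char_vocab), Dc, scale=0.5),
        "conv_w": init(3 * Dc, F),
        "conv_b": Tensor(np.zeros(F), requires_grad=True),
        "fw_wx": init(Din, 4 * H), "fw_wh": init(H, 4 * H),
        "fw_b": Tensor(np.zeros(4 * H), requires_grad=True),
        "bw_wx": init(Din, 4 * H), "bw_wh": init(H, 4 * H),
        "bw_b": Tensor(np.zeros(4 * H), requires_grad=True),
        "proj_w": init(2 * H, T),
        "proj_b": Tensor(np.zeros(T), requires_grad=True),
        "trans": Tensor(rng.normal(0, 0.01, size=(T + 2, T + 2)),
                        requires_grad=True),
    }
    if pretrained:
        for w, i in word_vocab.items():
            if w in pretrained and pretrained[w].shape[0] == D:
                params["word_emb"].data[i] = pretrained[w]

    model = TaggerModel(word_vocab, char_vocab, tags, cfg, params)
    opt = Adam(list(params.values()), lr=cfg.lr)
    order = np.arange(len(corpus))
    model.loss_history: list[float] = []
    for _epoch in range(cfg.epochs):
        rng.shuffle(order)
        total = 0.0
        for si in order:
            loss = model._sentence_loss(corpus[si])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        mean_loss = total / len(corpus)
        model.loss_history.append(mean_loss)
        if mean_loss < cfg.stop_at_zero_loss:
            break
    return model


def tag(model: TaggerModel, text: str) -> list[Mention]:
    """Tag free text and return entity mentions with character offsets."""
    return model.tag_text(text)
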