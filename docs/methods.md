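# Methods

This note documents the models behind `medireader`, the defaults that
matter, the numerical choices, and what the synthetic data does and does not
establish.

## Literacy measurement (3PL IRT)

**Model.** A person `j` answers item `i` correctly with probability
`P_ij = c_i + (1 − c_i) σ(a_i (θ_j − b_i))`, where `σ` is the logistic
function, `a > 0` is discrimination, `b` is difficulty on the ability scale,
and `c ∈ [0, 1)` is the guessing lower asymptote. Abilities are treated as a
random effect with a standard-normal population distribution, which fixes
the scale: θ = 0 is the population median, and the two-level literacy call
is high for θ ≥ 0, low for θ < 0 (the boundary is assigned to high; the
median is "average", and a tie-break had to pick a side).

**Ability estimation** is EAP: the posterior mean and SD of θ under the
N(0,1) prior, computed on a fixed 61-point grid spanning [−6, 6] with
prior-weighted quadrature. EAP is preferred to MLE because short screening
tests routinely produce all-correct/all-wrong patterns on which the MLE
diverges. The 61-point default agrees with a 10,001-point dense-grid oracle
to better than 1e−7 on the item sets we test (the integrand is smooth and
effectively band-limited); the grid is configurable. Zero usable responses
return the prior itself (θ = 0, se = 1).

**Calibration** is marginal EM (Bock–Aitkin): the E-step computes each
person's posterior over the quadrature grid, the M-step refits each item's
(a, b, c) against expected correct/attempted counts per node with L-BFGS-B
and an analytic gradient, warm-started at the previous estimates. An M-step
result is only accepted if it does not worsen that item's expected
complete-data objective, so EM ascent holds numerically, not just in exact
arithmetic. Convergence is declared when the objective changes by less than
1e−5 (default; max 500 iterations).

By default the guessing parameter carries a Beta(5, 17) prior (mode 0.2)
and the estimate is Bayes-modal rather than pure maximum likelihood. The
3PL `c` is notoriously weakly identified — easy items in particular contain
almost no information about their guessing floor, and errors in `c`
propagate into `a` — and a weak prior on `c` is the standard default in
established IRT software for exactly this reason. In a 2000-person × 30-item
recovery simulation the prior cuts RMSE(b) from ~0.21–0.25 to ~0.13–0.15
and lifts the correlation of estimated with true discrimination from
0.79–0.96 to 0.84–0.97 across seeds. `ThreePLResults.loglik_path` records
the objective the EM ascends (marginal log-likelihood plus log prior); it
is non-decreasing by construction. `marginal_loglik_path` holds the
likelihood alone, and setting `c_prior=None` gives pure MML, in which case
the two coincide. Bounds: a ∈ [0.05, 5], b ∈ [−6, 6], c ∈ [0, 0.5]; the
upper c bound prevents the known non-identifiability of simultaneous high
guessing and low discrimination. Columns that are constant among observed
entries carry no item information and are excluded with a warning.

**Test shortening** first drops items with a ≤ a_min (default 0.2 —
"cannot distinguish" is not a sharp threshold, so it is configurable), then
greedily selects the n items maximizing the mean total Fisher information
over the ability grid. Item information is additive across items, so greedy
selection provably equals the brute-force best subset; the tests verify
this against exhaustive enumeration on banks of up to 6 items.

## Entity recognition (BiLSTM-CNN-CRF)

Each token is encoded by a word embedding (case-insensitive vocabulary,
UNK for unseen words) concatenated with a character-level feature vector: a
width-3 convolution over character embeddings (PAD-padded) followed by
tanh and max-over-time pooling. A bidirectional LSTM produces contextual
states whose concatenation is projected to per-tag emission scores. A
linear-chain CRF with explicit start/stop states supplies the sequence
model: the forward recursion in log space computes the partition function,
Viterbi decodes the argmax path, and training minimizes the exact negative
log-likelihood (logZ − gold path score) per sentence with Adam
(lr 0.02 default) in a seeded order.

Numerical/design choices:

- The whole network runs on an in-repo reverse-mode autodiff engine over
  float64 numpy arrays (`medireader/_autograd.py`), verified against
  central finite differences. Desk-scale models make exactness and
  determinism more valuable than GPU throughput.
- Tags are BIO over {Disease, Problem, Drug, Test}. Constrained decoding
  (illegal BIO transitions forced to −∞) is on by default, so decoded
  sequences are always structurally valid.
- Viterbi ties resolve to the lowest tag index at every step; a fully tied
  instance returns the lexicographically smallest path. This makes decoding
  reproducible bit-for-bit.
- Default sizes (word 32, char 16, 24 filters, hidden 32) are the smallest
  round figures that reliably memorize a 30-sentence corpus within 200
  epochs; training stops early once mean sentence loss falls below 1e−3.
- Models serialize to a single JSON artifact (vocabularies + parameters +
  config); save/load round-trips predictions exactly.
- The tokenizer splits word characters and single punctuation marks while
  tracking character offsets (0-based, half-open, Unicode code points);
  it is pluggable.

Pretrained embeddings in the standard text format ("word v1 v2 …") can be
injected at training time; by default embeddings are randomly initialized,
which suffices at fixture scale.

## Entity linking

**Candidate generation.** Every (concept, alias) surface is normalized
(NFC, casefold, whitespace collapse), `#`-padded at the boundaries (so
surfaces shorter than 3 characters still produce n-grams), decomposed into
character 3-grams, and encoded as a TF-IDF vector with
`idf = log((1+N)/(1+df)) + 1` over the N alias strings, L2-normalized
(scikit-learn's smooth-idf convention, stated explicitly so test values are
bit-stable). n-grams seen in fewer than `min_count` alias strings are
dropped; the default `min_count = 1` keeps everything, which at desk scale
guarantees that a unique alias never encodes to a zero vector (10 is a
reasonable setting for vocabularies of UMLS scale). Mentions are encoded
identically and candidates ranked by exact cosine over all stored vectors —
an exhaustive kNN, which doubles as its own oracle; ties break by concept
id. k defaults to 25. A mention with no in-vocabulary n-grams yields an
empty candidate set (logged, not an error), and terms on the medical
stop-word list are discarded before linking.

**Disambiguation.** Each concept carries a sense profile: a sparse count
vector of unigrams, adjacent bigrams, and positional collocations
((offset, token) pairs for offsets −2, −1, +1, +2 around the mention)
aggregated from its KB definition and any labeled training contexts
(window ±5 tokens). The mention's context is encoded the same way and the
candidate with maximal cosine wins; when every sense scores zero (empty or
uninformative context) the generation ranking stands. This is deliberately
unsupervised-capable: definitions alone separate senses whose vocabularies
differ, and labeled contexts sharpen the profiles when available.

## Term difficulty

Gold labels derive from a 6-annotator panel by the exact rule: 6 positive
(understood) votes → easy, 4–5 → medium, fewer than 4 → difficult.

Features per term: syntactic category from a small rule tagger
(abbreviation for short all-caps tokens, suffix heuristics for
adjectives/adverbs/verbs, noun as the fallback for isolated terms);
character and syllable counts; first matching medical prefix and suffix
from a shipped inventory (longest match); consonant/vowel/other counts and
percentages (vowels are a,e,i,o,u; spaces and punctuation count as other;
the three counts partition the length and the percentages sum to 100);
presence in a general-language lexicon; general-corpus and medical-KB
frequencies (plain-text tables — the original web-scale frequency services
are not reproducible, so the lookups are pluggable files with neutral
defaults of zero); KB semantic types; and an optional dense embedding
(zero vector when absent). Syllables are maximal aeiouy groups with a
trailing silent-e correction and a floor of one.

The default classifier couples a character-level encoder over the term
(width-3 CNN + BiLSTM on the shared autodiff engine) with the standardized
dense feature vector, concatenated before a softmax layer; cross-entropy,
Adam, seeded order, early stop at mean loss 1e−3. The dense features and
the learned encoder are combined by concatenation before the output layer.
A logistic-regression backend over the dense features alone is provided as
a lightweight alternative.

## Annotation pipeline

Order of operations: tag → resolve overlapping spans (longest wins,
leftmost on ties) → drop stop-word surfaces → classify difficulty → apply
the literacy policy (high: difficult only; low: medium + difficult; easy
never) → generate candidates → disambiguate → expand depth-1 relations
(instance_of, subclass_of, part_of, has_part, plus associative edges).
Filtering before linking minimizes work and matches the stop-word-removal
contract. Mentions with empty candidate sets are dropped. Output is
canonical JSON (sorted keys), so identical artifacts and seed give
byte-identical output; the optional HTML rendering is presentational only.
The policy is monotone by construction: a low-literacy annotation set is
always a superset of the high-literacy set for the same document and
artifacts.

## Synthetic data: what it emulates, and what it does not

The generators stand in for licensed or unreproducible resources: a UMLS- /
Wikidata-like vocabulary, an annotated clinical corpus, screening-test
response data, and a human-voted difficulty dataset. All generators are
pure functions of (spec, seed) and their outputs pass the consuming
modules' validators.

- **KB**: pseudo-medical names built from pronounceable syllables plus real
  medical affixes; 1–4 aliases each; taxonomic relations forming a forest
  plus sparse associative edges; alias ambiguity controlled exactly — a
  configurable fraction of alias strings is shared by two concepts.
- **Corpus**: templated filler tokens around embedded KB aliases with BIO
  tags; per-sentence filler counts are tied to entity token counts so
  overall entity density tracks the spec (±10% at 1000 tokens).
- **Responses**: θ ~ N(0,1), entries Bernoulli(P_ij) from the 3PL model —
  exactly the model being fitted, so calibration tests are pure
  parameter-recovery checks. Item banks draw a ~ U(0.8, 2.2),
  b ~ U(−2, 1), c ~ U(0.05, 0.25); difficulties skew low because the
  emulated screening instrument is built predominantly from easy questions
  so that it can separate readers at the low-literacy end. Defaults:
  30 items, 2000 persons.
- **Difficulty terms**: easy = short common lexicon words, medium = bare
  2-syllable pseudo-words, difficult = long pseudo-words with medical
  prefix and suffix; labels come from 6 simulated Bernoulli votes
  (positive-vote probabilities 0.99 / 0.80 / 0.25 per intended class)
  passed through the real vote rule, so label noise behaves like a real
  panel.

**Limitations.** Passing on this data shows the algorithms are implemented
correctly, not that they reach production accuracy on clinical English: the
corpus has no real clinical syntax, misspellings, or nested entities; the
tagger evaluation is memorization, not generalization; sense profiles in
the WSD fixture are separable by construction; pseudo-term difficulty
features are cleaner than real lexical-complexity data; and the KB is far
smaller and more regular than UMLS. Recovery results for the IRT module are
simulation-based and conditional on the 3PL being the true model. The
measured quantities in `scripts/acceptance.py` are correctness and
recovery properties, not clinical performance claims.
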