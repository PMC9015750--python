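# medireader

Readers with low health literacy struggle with clinical documents — discharge
instructions, physician notes, consent forms — because those documents are
dense with specialist vocabulary. `medireader` is a library and CLI that
personalizes medical-text annotation to the reader: it estimates the reader's
health literacy from a short screening test, finds the medical terms in a
document, decides which of them *this* reader is likely to stumble on, links
those terms to a knowledge base, and attaches plain-language definitions and
related concepts.

The pipeline has four statistical/algorithmic cores:

1. **Literacy screening (IRT).** Responses to screening items follow the
   3-parameter-logistic model
   `P_ij = c_i + (1 − c_i) / (1 + exp(−a_i(θ_j − b_i)))` with discrimination
   `a`, difficulty `b` and guessing floor `c`; abilities `θ` carry a standard
   normal population prior, so θ = 0 is the 50th percentile. The package
   calibrates item banks by marginal maximum likelihood EM
   (`irt.ThreePLModel(...).fit()` → `ThreePLResults` with `summary()`),
   scores respondents by EAP quadrature, classifies literacy as high
   (θ ≥ 0) or low (θ < 0), and shortens tests by selecting the items with
   the highest average Fisher information
   `I(θ) = a²(Q/P)(P − c)²/(1 − c)²`.
2. **Entity recognition.** A BiLSTM-CNN-CRF tagger: width-3 character CNN
   with max-over-time pooling + word embeddings → bidirectional LSTM →
   linear-chain CRF with exact forward normalization and Viterbi decoding,
   over BIO tags for {Disease, Problem, Drug, Test}. It runs on the
   package's own numpy autodiff engine — no deep-learning framework needed.
3. **Entity linking.** Candidate generation encodes every KB alias as an
   L2-normalized TF-IDF vector of character 3-grams (`#`-padded) and ranks
   concepts by exact cosine kNN; ambiguous mentions are resolved by a
   vector-space word-sense-disambiguation model over unigram, bigram and
   positional-collocation context features.
4. **Term difficulty.** Terms are easy / medium / difficult. Gold labels
   come from a 6-annotator vote rule (6 positive → easy, 4–5 → medium,
   <4 → difficult); prediction combines surface features (characters,
   syllables, medical affixes, consonant/vowel mix, lexicon presence,
   corpus frequencies, semantic types) with a learned character encoder.
   The annotation policy is literacy-conditioned: high-literacy readers see
   only difficult terms annotated, low-literacy readers see medium and
   difficult; easy terms are never annotated.

A synthetic-data module (`medireader.synth`) generates every input the
pipeline needs — knowledge bases with controlled alias ambiguity,
gold-tagged corpora, 3PL response matrices, vote-labeled difficulty data —
so everything is testable offline with no licensed resources.

## Worked example

Generate a 20-concept knowledge base, a 30-sentence tagged corpus, train the
tagger, and annotate a document for a low-literacy reader:

```bash
medireader synth kb --seed 7 --n-concepts 20 --out kb.jsonl
medireader synth corpus --kb kb.jsonl --seed 7 --out train.conll
medireader synth difficulty --seed 7 --out terms.csv
medireader ner train --corpus train.conll --out model.json --seed 3
# -> trained on 30 sentences; final loss 0.0010; saved to model.json
medireader annotate --text doc.txt --literacy low --kb kb.jsonl \
    --ner-model model.json --difficulty-data difficulty.csv --out doc.json
# -> 3 annotations written to doc.json
```

The output JSON holds the original text plus one record per annotated span:

```json
{"concept_id": "S0006",
 "definition": "A chemical of the moke region characterized by paso and vifi.",
 "difficulty": "difficult", "start": 0, "end": 12,
 "surface": "cardiozukisu", "related": []}
```

meaning: characters 0–12 of the document ("cardiozukisu", a generated
pseudo-drug name) were recognized as a medical entity, classified difficult
(so annotated for every reader), linked to KB concept `S0006`, and given
that concept's definition. Rerunning with `--literacy high` drops any
medium-difficulty annotations; easy terms never appear.

Scoring a screening test and shortening it:

```bash
medireader literacy calibrate --responses resp.csv
# 3PL Marginal Maximum Likelihood Calibration
# persons: 200   items fitted: 30   excluded: 0
# log-likelihood: -3000.993   EM iterations: 43   converged: True
#            a        b        c
# Q01   0.8507  -1.3572   0.2102
# ...
medireader literacy score --items items.csv --responses resp.csv
# p00000  theta=+0.360  se=0.328  literacy=high
medireader literacy shorten --items items.csv -n 5
# Q29 Q08 Q25 Q07 Q16
```

`theta=+0.360` places the respondent just above the population average, so
they are screened as high literacy and will only see difficult terms
annotated.

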