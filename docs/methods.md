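# Methods

## Problem and scope

`biosentsim` estimates the semantic similarity of sentence pairs from
biomedical literature and evaluates any such estimator intrinsically:
scores are correlated (Pearson's *r*, Spearman's *r_s*) against averaged
human expert annotations on a 0–4 scale. The package covers the full
workflow — corpus preparation, string metrics, embedding-based scoring,
score combination, evaluation, and a contradiction probe — with a
synthetic-data generator that makes every stage runnable and testable at
desk scale. Training large neural sentence encoders on a full open-access
article corpus is out of scope; such models plug in through the
`WordVectorTable` (word2vec text format) and `SentenceEncoder` adapters.

## Corpus preparation

Raw article text is segmented into sentences, tokenized, and written one
sentence per line. Segmentation is a deterministic rule (terminal
punctuation followed by whitespace and an upper-case letter or digit,
with an abbreviation exception list covering "e.g.", "Fig.", single-letter
genus initials, etc.); it is pluggable, so a statistical segmenter can be
substituted without touching anything downstream.

Post-processing applies two heuristics that demonstrably matter for
article dumps:

* **Length filter** — lines with **fewer than 200 characters** are kept
  (strict `<`; a 200-character line is removed). Over-long lines in
  full-text dumps are dominated by tables and other non-prose content
  that degrades embedding training. The threshold is configurable
  (`PreprocessConfig.max_line_chars`).
* **Hyphen splitting** — hyphens joining two alphanumeric neighbours
  become spaces; leading/trailing hyphens are stripped. Restricting the
  split to alphanumeric neighbours preserves gene-symbol-like tokens and
  guarantees the multiset of non-hyphen characters is unchanged.

Stopword and punctuation removal (the eight marks `. , : ; ? ! / -`) is
applied where **string metrics** are computed, not to the training
corpus: embedding trainers benefit from seeing function words as context,
while set-overlap metrics are only diluted by them. The packaged stopword
list (~150 common English words) is data, not code — the choice of list
measurably shifts string-metric correlations, so callers can substitute
their own via `PreprocessConfig(stopword_list=...)` or a file. Lowercasing
defaults to on for all tokenized processing.

Pipeline order for string-metric scoring: hyphen splitting → tokenization
→ lowercasing → stopword/punctuation removal, with q-grams extracted from
the stripped tokens re-joined by single spaces. The interleaving of
hyphen splitting with segmentation is not externally constrained;
applying it before tokenization is this package's choice and is applied
identically everywhere.

## String metrics

* **Jaccard** over the two sentences' unique-token sets:
  `J(A,B) = |A∩B| / |A∪B|`; defined as 0 (with a logged warning) when
  both sets are empty.
* **Q-gram similarity** with character grams and q = 3 by default (word
  grams via `items="word"`). The definition is asymmetric — matches
  counted by multiset intersection, divided by the number of possible
  q-grams of the *first* string — and is implemented as written, with
  sentence 1 of a pair as the reference. Because the asymmetry is a
  genuine ambiguity (nothing pins down which sentence is the reference,
  or whether directions were averaged), a `symmetrize="mean"` option
  averages both directions. No sentinel padding is used: a reference
  string shorter than q scores 0.

Multiset (rather than set) gram counting is the standard q-gram distance
convention and the one implemented; each gram occurrence matches at most
once.

## Embeddings, pooling, cosine

`WordVectorTable` provides per-token vectors; sentence vectors are formed
by element-wise **max, min, sum or mean** pooling over the vectors of the
sentence's in-vocabulary tokens ("average" is accepted as an alias of
mean). OOV tokens are skipped and counted — never zero-filled — and a
sentence with no in-vocabulary token raises and is surfaced as a missing
score. Max pooling is the conventional default for fastText-style tables;
note that mean and sum pooling give *identical* cosine scores (they
differ by a positive scalar), which the tests assert.

Cosine similarity is the scorer for all vector representations; the
zero vector raises rather than returning an arbitrary value, and the
evaluation layer maps that to a flagged missing score.

The in-repo trainer (`train_word_table`) builds **PPMI–SVD vectors**: a
symmetric within-window co-occurrence count matrix over the
`min_count`-filtered vocabulary, the positive pointwise-mutual-information
transform `max(0, log p(i,j)/(p(i)p(j)))`, and a truncated dense SVD with
word vectors `U_d · sqrt(S_d)`. This count-based factorisation is a
classical distributional embedding method whose geometry closely tracks
negative-sampling skip-gram, and it is exactly reproducible — no
asynchronous SGD, no ordering effects — which suits a pipeline whose
tests assert byte-level determinism. Defaults: dimension 100 (20 in the
desk-scale test world), window 5, `min_count` 5 (the standard
speed/quality compromise that drops hapax-dominated vocabulary), seed
recorded in provenance together with a config hash. `epochs` and n-gram
settings are accepted for config-surface compatibility with iterative
trainers and recorded, but the single-shot SVD ignores them.

`BagOfWordsEncoder` (one-hot token counts over a fixed vocabulary) is the
reference lexical-overlap encoder used by the contradiction probe.

## Combiners

* **Unsupervised hybrid**: the arithmetic mean of the per-pair scores of
  several metrics. String-metric scores enter the mean at face value
  alongside cosines — Jaccard and q-gram are not cosines, and averaging
  the scores as given is the only coherent reading of a hybrid mean.
* **Supervised**: unpenalised OLS of gold on the feature columns,
  `y = b₀ + Σⱼ bⱼ xⱼ`, requiring ≥ k+2 rows, a non-constant gold column
  and a full-rank design (the error names the collinear features).
  Because an ~100-pair benchmark makes the in-sample / held-out
  distinction consequential and no single protocol is canonical, the
  package always reports both: the in-sample fit and seeded k-fold
  (default 10) cross-validated predictions, labelled separately.

Two feature presets are shipped: `hybrid` (jaccard, qgram,
pv_dbow_cosine, sent2vec_cosine) and `supervised` (jaccard, qgram,
sent2vec_cosine, pv_dm_cosine, skipthoughts_cosine, fasttext_cosine),
matching the two standard configurations of this workflow.

## Evaluation

Benchmarks are TSV files (`pair_id, sentence1, sentence2, score, subset`,
header required, score in [0, 4] or empty); the dialect is the package's
own, with lossless round-trip guaranteed by tests, and an importer hook
is simply `read_benchmark`'s pluggable caller side. Correlations use
scipy's Pearson and Spearman (mid-ranks for ties) behind `pearson` /
`spearman` wrappers that reject degenerate inputs (n < 3 or zero
variance) explicitly. Reports headline Pearson's *r*; Spearman stays in
the JSON. Unscorable pairs are excluded from the correlation and counted
(`n_missing`); imputing 0 would distort *r* unpredictably, so it is never
done, and a report with > 50 % missing raises.

The **contradiction probe** compares per-model mean cosine over three
subsets: high-similarity pairs (gold ≥ 3.5, inclusive threshold),
negation pairs and antonym pairs. It reports means, subset sizes, skipped
pairs and an `ordering_flag` that is true only when the high-similarity
mean strictly exceeds both contradiction-subset means — i.e. when the
model orders the subsets as a contradiction-aware system should. No
significance test is attached: with subsets of 7–13 pairs such a test
would be meaningless.

## Synthetic data: what it emulates, and what it does not

The generators produce, deterministically per seed:

* a **topic-structured corpus** (default 5 000 sentences, 600-token
  vocabulary in 6 disjoint topics, sentence lengths 6–14): every prose
  line draws all tokens from one topic, so co-occurrence encodes topic
  membership and a correctly trained embedding separates topics. A
  configured fraction (default 5 %) of lines are ≥ 200-character
  pseudo-table lines — numbers and tokens, no sentence structure — so the
  length filter removes an exactly known count; 10 % of prose lines carry
  a hyphenated compound for the splitting step.
* a **benchmark** (default 100 pairs) whose pairs have unique-token
  overlap o ∈ {0, 0.1, …, 1.0} realised *exactly* as the Jaccard index of
  the two token sets (intersection I and union 10 drawn from one topic;
  low-overlap pairs mix two topics so embedding scores also track gold),
  with gold = clip(4·o + N(0, σ), 0, 4). The default σ = 0.25 keeps gold
  clearly overlap-driven while exercising the noise-handling paths; σ = 0
  makes Jaccard-vs-gold correlation exactly 1, a construction guarantee
  the acceptance checks use.
* **contradiction subsets**: 13 negation pairs (negation inserted before
  the main verb — infinitival site preferred, else after the first
  auxiliary; already-negated or siteless sentences are skipped) and 7
  antonym pairs (exactly one keyword swapped using a self-inverse antonym
  lexicon), both guaranteed ≥ 0.8 raw unique-token Jaccard with their
  originals; plus an 11-pair **high-similarity reference** subset with
  gold ≥ 3.5 but only 0.4–0.6 token overlap, emulating human-annotated
  paraphrases whose equivalence of meaning does not come from shared
  wording.

What the synthetic world does *not* emulate: real benchmarks' gold is not
a function of lexical overlap (that is exactly why high-quality neural
models beat string metrics there, a gap the synthetic benchmark cannot
show); vocabulary is tiny and Zipf-free; sentences have no syntax beyond
the negation templates. Passing tests therefore demonstrate that each
component computes what it claims and that the pipeline's qualitative
phenomena (overlap drives string metrics; topic structure drives
embedding cosine; lexical-overlap models rate contradictions above
paraphrases) are reproduced — not that any particular correlation level
carries over to real literature.

The contradiction fixture sentences are synthetic, hand-written
single-clause statements in the style of biomedical citing sentences; the
negation rule set is deliberately minimal (infinitival and auxiliary
negation only), matching the restriction to simple declarative syntax
rather than attempting general negation handling.

## Numerical choices and degenerate inputs

* Jaccard of two empty sets → 0 with a logged warning (0/0 guard).
* Q-gram reference profile empty → 0 with a logged warning.
* Cosine of a zero vector → error, mapped to a missing score downstream.
* OLS rank deficiency → error naming the collinear features (smallest
  singular vectors' support); constant gold → error.
* Correlations: n < 3 or zero variance → error, never NaN.
* SVD sign indeterminacy does not affect any reported quantity (cosines
  are invariant to a global orthogonal transform of the factorisation;
  determinism is additionally pinned by using the dense LAPACK SVD).
* All seeds are explicit; generators and cross-validation folds derive
  from a single integer seed.

## Problem sizes

The test suite and the acceptance script run the pipeline at: corpus
5 000 sentences (vocabulary 600, embedding dimension 20, `min_count` 5),
benchmark 100 pairs, negation 13 / antonym 7 / high-similarity 11 pairs,
10-fold cross-validation. These sizes are the package's desk-scale
defaults; the code paths are size-agnostic.

## Known limitations

* The rule-based segmenter is English-specific and abbreviation-list
  driven; swap in a statistical segmenter via the `segmenter` argument
  for production corpora.
* PPMI–SVD training materialises a dense vocabulary × vocabulary matrix;
  it is meant for vocabularies up to a few tens of thousands of types.
  For larger corpora, train externally and load the word2vec text file.
* The q-gram reference-string asymmetry means pair order matters unless
  `symmetrize="mean"` is requested.
* fastText-style subword composition for OOV tokens is not implemented
  in-repo; an adapter encoder can provide it.
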