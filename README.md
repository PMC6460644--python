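# biosentsim

Sentence-level semantic similarity estimation for biomedical text.

Biomedical literature mining needs a way to quantify how close two
sentences are in *meaning* — for retrieval, summarisation and
question-answering — and the standard way to validate such a metric is
intrinsic evaluation: correlate its scores with human expert judgments on
an annotated benchmark of sentence pairs (each pair rated on a continuous
0–4 scale, 0 = unrelated, 4 = equivalent). `biosentsim` implements the
full workflow:

* **Corpus preparation** — sentence segmentation and tokenization of raw
  article text into a sentence-per-line training corpus, with the
  post-processing heuristics that matter for article dumps: dropping
  lines of ≥ 200 characters (mostly table debris, not prose) and
  splitting hyphenated compounds (`anti-HER2` → `anti HER2`).
* **String-based metrics** — the Jaccard index over unique tokens,
  `J(A,B) = |A∩B| / |A∪B|`, and q-gram similarity (shared character
  q-grams of the pair divided by the possible q-grams of the first
  sentence, q = 3 by default), both computed after stopword/punctuation
  removal and case folding.
* **Embedding-based scoring** — a `WordVectorTable` contract with
  element-wise **max / min / sum / mean pooling** of word vectors into
  sentence vectors, a `SentenceEncoder` adapter contract for externally
  trained whole-sentence models, and cosine similarity
  `cos(θ) = A·B / (‖A‖‖B‖)`. The in-repo trainer builds deterministic
  count-based vectors (positive-PMI co-occurrence matrix + truncated
  SVD); externally trained skip-gram / CBOW / fastText tables load from
  the standard word2vec text format.
* **Combiners** — the unsupervised hybrid mean of several metrics'
  scores, and a supervised ordinary-least-squares regression
  `y = b₀ + Σⱼ bⱼxⱼ` of gold scores on the per-metric scores, with both
  in-sample and seeded 10-fold cross-validated reporting.
* **Evaluation harness** — Pearson *r* (headlined) and Spearman *r_s*
  between predicted and gold scores; pairs a model cannot score are
  excluded and counted, never imputed.
* **Contradiction probe** — mean cosine on negation pairs (a negation
  inserted before the main verb), antonym pairs (one keyword swapped for
  its antonym) and a high-similarity reference subset (gold ≥ 3.5).
  Lexical-overlap-driven models rate the contradiction subsets *above*
  genuinely similar pairs, because a negated sentence shares nearly all
  of its tokens with the original; the probe measures exactly that
  failure mode.
* **Synthetic fixtures** — seeded generators for topic-structured
  corpora, benchmarks with construction-controlled token overlap, and
  rule-generated contradiction subsets, so the whole pipeline runs and is
  tested at desk scale without any external download.

## Worked example

```python
from biosentsim import preprocess_sentence, sentence_jaccard, sentence_qgram, negate_sentence

s1 = "The up-regulation of miR-146a was also detected in cervical cancer tissues."
s2 = "The expression of miR-146a has been found to be up-regulated in cervical cancer."
print(preprocess_sentence(s1).tokens)
print(f"jaccard = {sentence_jaccard(s1, s2):.3f}")
print(f"qgram   = {sentence_qgram(s1, s2):.3f}")

neg = negate_sentence("Rip1 was reported to interact with rip3.")
print("negated:", neg)
print(f"jaccard(original, negated) = {sentence_jaccard('Rip1 was reported to interact with rip3.', neg):.3f}")
```

prints

```
('regulation', 'mir', '146a', 'also', 'detected', 'cervical', 'cancer', 'tissues')
jaccard = 0.364
qgram   = 0.600
negated: Rip1 was reported to not interact with rip3.
jaccard(original, negated) = 1.000
```

The two paraphrases about miR-146a share about a third of their unique
content tokens (Jaccard 0.36) even though they mean nearly the same
thing, while the *contradictory* negated pair scores a perfect 1.0 —
"not" is a stopword, so string overlap cannot see the negation at all.
That asymmetry is the phenomenon the contradiction probe quantifies.

A full pipeline run from the shell:

```bash
biosentsim gen-fixtures --what corpus --seed 1 --out corpus.txt
biosentsim prep-corpus --input docs_dir --output corpus.txt   # or from your own .txt files
biosentsim train-embeddings --corpus corpus.txt --out vectors.txt --dim 100 --min-count 5
biosentsim gen-fixtures --what benchmark --seed 1 --out bench.tsv
biosentsim evaluate --benchmark bench.tsv --scorer cosine --model vectors.txt --pooling mean
biosentsim probe-contradictions --benchmark subsets.tsv --model vectors.txt
```

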