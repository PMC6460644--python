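"""Desk-scale synthetic corpora, benchmarks and contradiction subsets.

Every generator is a pure function of its config (seed included), producing
byte-identical text across runs.  The synthetic world is built so that each
downstream assumption of the pipeline holds *by construction*:

* the corpus is topic-structured — each line draws its tokens from one
  topic's vocabulary, so word co-occurrence encodes topic and a trained
  embedding separates topics;
* a configurable fraction of lines are over-long pseudo-table lines (the
  non-prose debris found in full-text article dumps) so the length filter
  has real work to do, and a fraction of sentences contain hyphenated
  compounds for the hyphen-splitting step;
* benchmark pairs are built with an exact unique-token overlap o ∈ [0, 1]
  and gold = 4·o + Gaussian noise clipped to [0, 4], so at zero noise the
  Jaccard index reproduces gold/4 exactly;
* negation pairs insert a single negation before the main verb and antonym
  pairs swap exactly one keyword, so both keep raw unique-token Jaccard
  ≥ 0.8 with their originals — the structural property that makes
  lexical-overlap models rate contradictions above mere paraphrases;
* the high-similarity reference pairs are paraphrase-like: high gold score
  (≥ 3.5) but only moderate lexical overlap, as in human-annotated data
  where equivalence of meaning does not require identical wording.

Default sizes mirror the standard benchmark shapes: 100 main pairs, 13
negation pairs, 7 antonym pairs, 11 high-similarity reference pairs.
"""

from __future__ import annotations

import logging
import math
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import BenchmarkPair, write_benchmark
from .stopwords import DEFAULT_STOPWORDS

__all__ = [
    "GeneratorConfig",
    "AntonymLexicon",
    "DEFAULT_ANTONYM_LEXICON",
    "topic_vocabularies",
    "generate_corpus",
    "generate_benchmark",
    "generate_high_similarity_pairs",
    "negate_sentence",
    "generate_negation_pairs",
    "generate_antonym_pairs",
    "default_negation_sentences",
    "default_antonym_sentences",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-data world.

    ``overlap_noise`` is the σ of the Gaussian perturbation on benchmark
    gold scores (0 makes gold a deterministic function of token overlap);
    ``fraction_long_lines`` controls how many corpus lines are over-long
    pseudo-table lines, and ``fraction_hyphenated`` how many prose lines
    carry a hyphenated compound.
    """

    seed: int = 0
    vocab_size: int = 600
    n_topics: int = 6
    n_sentences: int = 5000
    sentence_length: tuple[int, int] = (6, 14)
    benchmark_size: int = 100
    overlap_noise: float = 0.25
    fraction_long_lines: float = 0.05
    fraction_hyphenated: float = 0.10
    max_line_chars: int = 200

    def __post_init__(self) -> None:
        if min(self.vocab_size, self.n_topics, self.n_sentences, self.benchmark_size) <= 0:
            raise ValueError("all counts must be positive")
        if self.overlap_noise < 0:
            raise ValueError("overlap_noise must be >= 0")
        for frac in (self.fraction_long_lines, self.fraction_hyphenated):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.sentence_length
        if not 1 <= lo <= hi:
            raise ValueError("invalid sentence_length range")
        if self.vocab_size < self.n_topics * max(20, hi + 6):
            raise ValueError(
                f"vocab_size {self.vocab_size} too small for {self.n_topics} topics"
            )


# --------------------------------------------------------------------------
# token inventory
# --------------------------------------------------------------------------

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu "
    "ka ke ki ko ku la le li lo lu ma me mi mo mu na ne ni no nu "
    "pa pe pi po pu ra re ri ro ru sa se si so su ta te ti to tu "
    "va ve vi vo vu za ze zi zo zu mir kin ras gen tox lys pro"
).split()


def _make_tokens(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic inventory of word-like, non-stopword, hyphen-free tokens."""
    tokens: list[str] = []
    seen: set[str] = set()
    while len(tokens) < n:
        k = int(rng.integers(2, 5))
        word = "".join(_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), k))
        if len(word) < 4 or len(word) > 12:
            continue
        if word in seen or word in DEFAULT_STOPWORDS:
            continue
        seen.add(word)
        tokens.append(word)
    return tokens


def topic_vocabularies(config: GeneratorConfig) -> list[list[str]]:
    """Disjoint per-topic token inventories, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    tokens = _make_tokens(config.vocab_size, rng)
    per = config.vocab_size // config.n_topics
    return [tokens[t * per:(t + 1) * per] for t in range(config.n_topics)]


# --------------------------------------------------------------------------
# corpus
# --------------------------------------------------------------------------

def generate_corpus(config: GeneratorConfig, path: str | Path) -> Path:
    """Write a topic-structured sentence-per-line corpus file.

    Exactly ``round(fraction_long_lines * n_sentences)`` lines are
    pseudo-table lines of ≥ ``max_line_chars`` characters (so the length
    filter removes exactly that many); every prose line draws all its
    tokens from a single topic's vocabulary and stays under the threshold.
    Byte-identical output for identical config.
    """
    rng = np.random.default_rng(config.seed)
    topics = topic_vocabularies(config)
    n_long = round(config.fraction_long_lines * config.n_sentences)
    n_prose = config.n_sentences - n_long
    lo, hi = config.sentence_length

    lines: list[str] = []
    for _ in range(n_prose):
        t = int(rng.integers(config.n_topics))
        length = int(rng.integers(lo, hi + 1))
        vocab = topics[t]
        idx = rng.choice(len(vocab), size=min(length, len(vocab)), replace=False)
        words = [vocab[int(i)] for i in idx]
        if rng.random() < config.fraction_hyphenated and len(words) >= 2:
            j = int(rng.integers(len(words) - 1))
            words[j:j + 2] = [words[j] + "-" + words[j + 1]]
        line = " ".join(words)
        while len(line) >= config.max_line_chars:  # construction guard
            words = words[:-1]
            line = " ".join(words)
        lines.append(line)

    for _ in range(n_long):
        t = int(rng.integers(config.n_topics))
        vocab = topics[t]
        cells: list[str] = []
        while sum(len(c) + 1 for c in cells) <= config.max_line_chars + 10:
            if rng.random() < 0.5:
                cells.append(str(int(rng.integers(0, 10000))))
            else:
                cells.append(vocab[int(rng.integers(len(vocab)))])
        lines.append(" ".join(cells))

    order = rng.permutation(len(lines))
    text = "".join(lines[int(i)] + "\n" for i in order)
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# benchmark
# --------------------------------------------------------------------------

_OVERLAP_UNION = 10  # union size of the unique-token grid; o = I / 10


def _overlap_pair(
    rng: np.random.Generator,
    topics: list[list[str]],
    intersection: int,
    same_topic: bool,
) -> tuple[list[str], list[str], float]:
    """Two token lists with unique-token Jaccard exactly intersection/10."""
    union = _OVERLAP_UNION
    a_excl = math.ceil((union - intersection) / 2)
    b_excl = union - intersection - a_excl
    t = int(rng.integers(len(topics)))
    vocab_a = topics[t]
    idx = rng.choice(len(vocab_a), size=intersection + a_excl, replace=False)
    drawn = [vocab_a[int(i)] for i in idx]
    shared, excl_a = drawn[:intersection], drawn[intersection:]
    if same_topic:
        pool = [w for w in vocab_a if w not in set(drawn)]
    else:
        t2 = (t + 1 + int(rng.integers(len(topics) - 1))) % len(topics)
        pool = topics[t2]
    idx_b = rng.choice(len(pool), size=b_excl, replace=False) if b_excl else []
    excl_b = [pool[int(i)] for i in idx_b]
    s1 = shared + excl_a
    s2 = shared + excl_b
    rng.shuffle(s1)
    rng.shuffle(s2)
    return s1, s2, intersection / union


def generate_benchmark(
    config: GeneratorConfig, path: str | Path | None = None
) -> list[BenchmarkPair]:
    """Benchmark pairs spanning the whole overlap spectrum [0, 1].

    Pair i has unique-token overlap o = (i mod 11)/10 realised exactly as
    the Jaccard index of the two sentences' token sets, and gold =
    clip(4·o + N(0, σ), 0, 4) with σ = ``overlap_noise``.  Low-overlap
    pairs mix two topics, so embedding-based scores also track gold.
    Writes the TSV dialect when *path* is given.
    """
    rng = np.random.default_rng(config.seed + 1)
    topics = topic_vocabularies(config)
    pairs: list[BenchmarkPair] = []
    for i in range(config.benchmark_size):
        intersection = i % (_OVERLAP_UNION + 1)
        o = intersection / _OVERLAP_UNION
        s1, s2, o_real = _overlap_pair(rng, topics, intersection, same_topic=o >= 0.5)
        gold = 4.0 * o_real + (
            float(rng.normal(0.0, config.overlap_noise)) if config.overlap_noise else 0.0
        )
        gold = float(np.clip(gold, 0.0, 4.0))
        pairs.append(
            BenchmarkPair(
                pair_id=f"pair{i + 1:04d}",
                sentence1=" ".join(s1) + ".",
                sentence2=" ".join(s2) + ".",
                gold=gold,
                subset="main",
            )
        )
    if path is not None:
        write_benchmark(pairs, path)
    return pairs


def generate_high_similarity_pairs(
    config: GeneratorConfig, n: int = 11, path: str | Path | None = None
) -> list[BenchmarkPair]:
    """Paraphrase-like reference pairs: gold ≥ 3.5, moderate word overlap.

    Emulates the high-similarity slice of a human-annotated benchmark,
    where near-equivalent meaning is expressed with partly different
    wording (unique-token overlap around 0.4–0.6).  This is the subset a
    contradiction-aware model should score *above* negation/antonym pairs.
    """
    rng = np.random.default_rng(config.seed + 2)
    topics = topic_vocabularies(config)
    pairs: list[BenchmarkPair] = []
    for i in range(n):
        intersection = 4 + i % 3  # o in {0.4, 0.5, 0.6}
        s1, s2, _ = _overlap_pair(rng, topics, intersection, same_topic=True)
        gold = float(rng.uniform(3.5, 4.0))
        pairs.append(
            BenchmarkPair(
                pair_id=f"hisim{i + 1:03d}",
                sentence1=" ".join(s1) + ".",
                sentence2=" ".join(s2) + ".",
                gold=gold,
                subset="high_similarity",
            )
        )
    if path is not None:
        write_benchmark(pairs, path)
    return pairs


# --------------------------------------------------------------------------
# contradiction subsets
# --------------------------------------------------------------------------

_INFINITIVE = re.compile(r"\bto\s+([a-z]+)", re.IGNORECASE)
_AUXILIARY = re.compile(
    r"\b(was|were|is|are|can|could|may|might|will|would|should|must|do|does|did|has|have|had)\b",
    re.IGNORECASE,
)


def negate_sentence(sentence: str) -> str | None:
    """Insert a negation before the main verb of a simple declarative.

    Two rules only, matching the restriction to simple syntax: infinitival
    negation ("to interact" → "to not interact") takes priority; otherwise
    "not" is inserted after the first auxiliary ("could be induced" →
    "could not be induced").  Returns None when the sentence is already
    negated or offers no insertion site.
    """
    if re.search(r"\bnot\b", sentence, re.IGNORECASE):
        return None
    m = _INFINITIVE.search(sentence)
    if m:
        return sentence[:m.start()] + "to not " + m.group(1) + sentence[m.end():]
    m = _AUXILIARY.search(sentence)
    if m:
        return sentence[:m.end()] + " not" + sentence[m.end():]
    return None


def generate_negation_pairs(
    sentences: Sequence[str], path: str | Path | None = None
) -> list[BenchmarkPair]:
    """Original/negated sentence pairs (subset label "negation").

    Sentences with no applicable negation site are skipped with a warning.
    """
    pairs: list[BenchmarkPair] = []
    for i, sent in enumerate(sentences):
        negated = negate_sentence(sent)
        if negated is None:
            logger.warning("no negation site in sentence %d: %r", i + 1, sent)
            continue
        pairs.append(
            BenchmarkPair(
                pair_id=f"neg{len(pairs) + 1:03d}",
                sentence1=sent,
                sentence2=negated,
                subset="negation",
            )
        )
    if path is not None:
        write_benchmark(pairs, path)
    return pairs


@dataclass(frozen=True)
class AntonymLexicon:
    """Keyword → antonym map used to flip a sentence's meaning."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        for a, b in self.pairs.items():
            if a == b:
                raise ValueError(f"token {a!r} maps to itself")
            if b in self.pairs and self.pairs[b] != a:
                raise ValueError(f"mapping not self-inverse at {a!r}/{b!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AntonymLexicon":
        """Two-column TSV (word, antonym); both directions are added."""
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            a, b = cols[0].strip().lower(), cols[1].strip().lower()
            mapping[a] = b
            mapping[b] = a
        return cls(mapping)


DEFAULT_ANTONYM_LEXICON = AntonymLexicon(
    {
        "induces": "inhibits",
        "inhibits": "induces",
        "impaired": "enhanced",
        "enhanced": "impaired",
        "increased": "decreased",
        "decreased": "increased",
        "activates": "represses",
        "represses": "activates",
        "promotes": "suppresses",
        "suppresses": "promotes",
        "upregulated": "downregulated",
        "downregulated": "upregulated",
        "positive": "negative",
        "negative": "positive",
    }
)


def generate_antonym_pairs(
    sentences: Sequence[str],
    lexicon: AntonymLexicon = DEFAULT_ANTONYM_LEXICON,
    path: str | Path | None = None,
) -> list[BenchmarkPair]:
    """Pairs where exactly one keyword is swapped for its antonym.

    The first token (in sentence order) found in the lexicon is replaced;
    all other tokens are left identical.  Sentences containing no keyword
    are skipped with a warning.
    """
    pairs: list[BenchmarkPair] = []
    for i, sent in enumerate(sentences):
        words = sent.split()
        hit = None
        for j, w in enumerate(words):
            key = w.strip(".,;:!?").lower()
            if key in lexicon.pairs:
                hit = (j, w, key)
                break
        if hit is None:
            logger.warning("no antonym keyword in sentence %d: %r", i + 1, sent)
            continue
        j, original, key = hit
        replacement = lexicon.pairs[key]
        if original[0].isupper():
            replacement = replacement.capitalize()
        swapped = words.copy()
        swapped[j] = replacement + original[len(key):]  # keep trailing punctuation
        pairs.append(
            BenchmarkPair(
                pair_id=f"ant{len(pairs) + 1:03d}",
                sentence1=sent,
                sentence2=" ".join(swapped),
                subset="antonym",
            )
        )
    if path is not None:
        write_benchmark(pairs, path)
    return pairs


# --------------------------------------------------------------------------
# default contradiction fixture sentences (synthetic, simple syntax)
# --------------------------------------------------------------------------

def default_negation_sentences() -> list[str]:
    """13 synthetic single-clause sentences with an obvious negation site."""
    return [
        "Tlr4 was reported to interact with myd88 in macrophages.",
        "Overexpression of braf was found to accelerate tumor growth in mice.",
        "The inhibitor was able to block downstream kinase signalling.",
        "Apoptosis could be induced by sustained activation of jnk.",
        "The mutant protein was predicted to bind the promoter region.",
        "Silencing of stat3 appeared to reduce the proliferation of tumor cells.",
        "The drug was observed to suppress cytokine release in vivo.",
        "Loss of pten is known to enhance signalling through the akt pathway.",
        "The transcript was confirmed to encode a functional ion channel.",
        "Methylation of the promoter was shown to silence gene expression.",
        "The complex is thought to stabilize the replication fork.",
        "Treatment with the agonist seemed to restore normal insulin secretion.",
        "The variant allele was demonstrated to impair receptor trafficking.",
    ]


def default_antonym_sentences() -> list[str]:
    """7 synthetic sentences, each containing one default-lexicon keyword."""
    return [
        "When expressed in primary fibroblasts, oncogenic kras induces premature senescence and durable growth arrest.",
        "Knockdown of dnmt3a led to impaired myeloid differentiation and preferential erythroid commitment in culture.",
        "Chronic exposure to the ligand increased receptor density at the synaptic membrane of cortical neurons.",
        "The fusion oncoprotein activates transcription of target genes controlling cell cycle progression.",
        "Hypoxia promotes angiogenic sprouting by stabilizing hif1a protein in endothelial cells.",
        "Expression of the transporter was upregulated in resistant tumor samples compared with matched controls.",
        "Deletion of the distal enhancer markedly decreased baseline transcription of the neighbouring locus in reporter assays.",
    ]
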