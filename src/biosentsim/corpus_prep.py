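"""Build a sentence-per-line training corpus from raw article text.

The corpus pipeline mirrors how large open-access article dumps are prepared
for embedding training: sentence boundary detection and tokenization, then
post-processing — dropping excessively long lines (mostly table content, not
prose) and splitting hyphenated compounds.  Stopword and punctuation removal
is a separate step applied where string-based metrics are computed, not to
the training corpus itself.

Sentence segmentation is rule-based (terminal punctuation plus an
abbreviation exception list) and deliberately pluggable: any callable
``str -> list[str]`` returning a partition of the document can be swapped in
via the ``segmenter`` argument where an external segmenter is preferred.
"""

from __future__ import annotations

import json
import re
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from .stopwords import DEFAULT_PUNCTUATION, DEFAULT_STOPWORDS

__all__ = [
    "TokenizedSentence",
    "CorpusLine",
    "CorpusStats",
    "PreprocessConfig",
    "segment_sentences",
    "segment_and_tokenize",
    "tokenize",
    "filter_long_lines",
    "split_hyphen_compounds",
    "remove_stopwords_and_punct",
    "preprocess_sentence",
    "build_corpus",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TokenizedSentence:
    """An ordered token sequence plus the raw string it came from."""

    raw: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class CorpusLine:
    """One sentence (or pseudo-sentence) of the corpus, one per output line."""

    text: str

    def __post_init__(self) -> None:
        if "\n" in self.text or "\r" in self.text:
            raise ValueError("corpus line must not contain line breaks")

    @property
    def char_length(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class CorpusStats:
    """Summary statistics of a post-processed corpus."""

    n_lines: int
    n_tokens: int
    n_unique_tokens: int
    mean_line_length: float
    max_line_length: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the corpus/string-metric preprocessing pipeline.

    ``max_line_chars`` is a *strict* upper bound: lines are kept only when
    shorter than the threshold.  ``punctuation_list`` defaults to the eight
    marks removed together with stopwords (full stop, comma, colon,
    semicolon, question mark, exclamation mark, slash, dash).
    """

    max_line_chars: int = 200
    split_hyphens: bool = True
    lowercase: bool = True
    stopword_list: frozenset[str] = DEFAULT_STOPWORDS
    punctuation_list: frozenset[str] = DEFAULT_PUNCTUATION

    def __post_init__(self) -> None:
        if self.max_line_chars <= 0:
            raise ValueError("max_line_chars must be positive")


# --------------------------------------------------------------------------
# segmentation and tokenization
# --------------------------------------------------------------------------

#: Abbreviations after which a full stop does not end a sentence.
ABBREVIATIONS: frozenset[str] = frozenset({
    "e.g", "i.e", "cf", "vs", "al", "et", "etc", "fig", "figs", "eq", "eqs",
    "ref", "refs", "no", "nos", "dr", "prof", "mr", "mrs", "ms", "st", "ca",
    "approx", "inc", "ltd", "vol", "pp", "chap", "sec", "resp",
})

# sentence end: terminal punctuation, optional closing quote/bracket,
# whitespace, then an upper-case letter or digit
_BOUNDARY = re.compile(r"[.!?][\"')\]]*\s+(?=[A-Z0-9])")
_TOKEN = re.compile(r"[^\W_]+(?:[-'’][^\W_]+)*|\S", re.UNICODE)


def _is_abbreviation_end(prefix: str) -> bool:
    """True if *prefix* ends with an abbreviation (boundary is spurious)."""
    m = re.search(r"([A-Za-z][A-Za-z.]*)\.$", prefix)
    if m is None:
        return False
    word = m.group(1).rstrip(".").lower()
    if word in ABBREVIATIONS:
        return True
    # single letters ("S. cerevisiae") and dotted initialisms
    return len(word) == 1 or "." in m.group(1)


def segment_sentences(document: str) -> list[str]:
    """Split *document* into sentence strings.

    The returned strings are exact slices of the document, so concatenating
    them (ignoring the whitespace stripped at slice edges) recovers the
    document's non-whitespace content.
    """
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(document):
        candidate = document[start:m.end()]
        if _is_abbreviation_end(candidate.rstrip()):
            continue
        piece = candidate.strip()
        if piece:
            sentences.append(piece)
        start = m.end()
    tail = document[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def tokenize(sentence: str) -> tuple[str, ...]:
    """Split a sentence into word and punctuation tokens.

    Hyphenated and apostrophe compounds stay single tokens here; hyphen
    splitting is a separate post-processing decision.
    """
    return tuple(_TOKEN.findall(sentence))


def segment_and_tokenize(
    document: str,
    segmenter: Callable[[str], list[str]] = segment_sentences,
) -> list[TokenizedSentence]:
    """Segment *document* into sentences and tokenize each.

    An empty (or whitespace-only) document yields an empty list.  Every
    returned sentence has at least one token.
    """
    out: list[TokenizedSentence] = []
    for raw in segmenter(document):
        tokens = tokenize(raw)
        if tokens:
            out.append(TokenizedSentence(raw=raw, tokens=tokens))
    return out


# --------------------------------------------------------------------------
# post-processing
# --------------------------------------------------------------------------

def filter_long_lines(
    lines: Sequence[CorpusLine], config: PreprocessConfig | None = None
) -> list[CorpusLine]:
    """Keep only lines strictly shorter than ``config.max_line_chars``.

    Excessively long lines in article dumps are dominated by table content
    rather than prose; dropping them improves embedding quality and training
    time.  Order is preserved; the result is a subsequence of the input, and
    the operation is idempotent.
    """
    config = config or PreprocessConfig()
    return [ln for ln in lines if ln.char_length < config.max_line_chars]


_HYPHEN_BETWEEN = re.compile(r"(?<=[0-9A-Za-z])-(?=[0-9A-Za-z])")


def split_hyphen_compounds(line: CorpusLine | str) -> CorpusLine:
    """Separate compound words connected by hyphens.

    Hyphens between alphanumeric neighbours become spaces ("anti-HER2" ->
    "anti HER2"); leading/trailing hyphens on tokens are stripped.  The
    multiset of non-hyphen, non-whitespace characters is unchanged.
    """
    text = line.text if isinstance(line, CorpusLine) else line
    parts: list[str] = []
    for tok in text.split():
        tok = _HYPHEN_BETWEEN.sub(" ", tok)
        for sub in tok.split():
            sub = sub.strip("-")
            if sub:
                parts.append(sub)
    return CorpusLine(" ".join(parts))


def remove_stopwords_and_punct(
    tokens: Iterable[str], config: PreprocessConfig | None = None
) -> tuple[str, ...]:
    """Drop stopwords (case-insensitive) and punctuation tokens.

    Relative order is preserved.  The result may be empty (an all-stopword
    sentence); callers scoring token sets must handle that.
    """
    config = config or PreprocessConfig()
    stop = {w.lower() for w in config.stopword_list}
    punct = set(config.punctuation_list)
    return tuple(
        t for t in tokens if t.lower() not in stop and t not in punct
    )


def preprocess_sentence(
    sentence: str, config: PreprocessConfig | None = None
) -> TokenizedSentence:
    """Full preprocessing of one raw sentence for string-metric scoring.

    Pipeline order: hyphen splitting (optional) -> tokenization ->
    lowercasing (optional) -> stopword/punctuation removal.
    """
    config = config or PreprocessConfig()
    text = sentence
    if config.split_hyphens:
        text = split_hyphen_compounds(CorpusLine(text.replace("\n", " "))).text
    tokens = tokenize(text)
    if config.lowercase:
        tokens = tuple(t.lower() for t in tokens)
    tokens = remove_stopwords_and_punct(tokens, config)
    return TokenizedSentence(raw=sentence, tokens=tokens)


# --------------------------------------------------------------------------
# corpus assembly
# --------------------------------------------------------------------------

def _iter_documents(documents: Iterable[str | Path]) -> Iterable[str]:
    for doc in documents:
        if isinstance(doc, Path):
            try:
                yield doc.read_text(encoding="utf-8")
            except OSError as exc:
                raise OSError(f"cannot read document {doc}: {exc}") from exc
        else:
            yield doc


def build_corpus(
    documents: Sequence[str | Path],
    output: str | Path,
    config: PreprocessConfig | None = None,
) -> tuple[Path, CorpusStats]:
    """Write a single sentence-per-line corpus file and compute its stats.

    Each document is segmented and tokenized; sentences are rewritten as
    space-joined token lines (lowercased and hyphen-split per *config*), and
    lines at or above ``max_line_chars`` characters are dropped.  Stopwords
    are retained — the training corpus keeps function words; removal belongs
    to string-metric scoring.  Deterministic for fixed input and config.
    """
    if not documents:
        raise ValueError("build_corpus requires at least one document")
    config = config or PreprocessConfig()

    lines: list[CorpusLine] = []
    for text in _iter_documents(documents):
        for sent in segment_and_tokenize(text):
            tokens = sent.tokens
            if config.lowercase:
                tokens = tuple(t.lower() for t in tokens)
            line = CorpusLine(" ".join(tokens))
            if config.split_hyphens:
                line = split_hyphen_compounds(line)
            if line.text:
                lines.append(line)

    lines = filter_long_lines(lines, config)

    output = Path(output)
    output.write_text("".join(ln.text + "\n" for ln in lines), encoding="utf-8")

    all_tokens = [t for ln in lines for t in ln.text.split()]
    lengths = [ln.char_length for ln in lines]
    stats = CorpusStats(
        n_lines=len(lines),
        n_tokens=len(all_tokens),
        n_unique_tokens=len(set(all_tokens)),
        mean_line_length=(sum(lengths) / len(lengths)) if lengths else 0.0,
        max_line_length=max(lengths, default=0),
    )
    return output, stats
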