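"""String-based sentence similarity: Jaccard index and q-gram similarity.

Both metrics operate on preprocessed sentences (lowercased, hyphen-split,
stopwords and punctuation removed).  The Jaccard index compares the *unique*
token sets A and B of the two sentences:

    J(A, B) = |A ∩ B| / |A ∪ B|

Q-gram similarity slides a window of q characters over each string and
counts shared q-grams.  As defined here it is asymmetric: the number of
q-gram matches against the second string is divided by the number of
possible q-grams of the *first* (reference) string.  A ``symmetrize="mean"``
option averages both directions.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass

from .corpus_prep import PreprocessConfig, preprocess_sentence

__all__ = [
    "QGramProfile",
    "jaccard_similarity",
    "qgram_profile",
    "qgram_similarity",
    "sentence_jaccard",
    "sentence_qgram",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QGramProfile:
    """Multiset of length-q character (or word) grams of one string."""

    grams: Counter
    q: int

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")

    @property
    def size(self) -> int:
        """Total gram count with multiplicity: max(0, len(s) - q + 1)."""
        return sum(self.grams.values())


def jaccard_similarity(a: Iterable[str], b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B| over unique tokens; 0.0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        logger.warning("jaccard_similarity: both token sets empty; returning 0")
        return 0.0
    return len(sa & sb) / len(union)


def qgram_profile(s: str, q: int, items: str = "char") -> QGramProfile:
    """Enumerate the contiguous length-q grams of *s*, with multiplicity.

    ``items="char"`` (default) slides over characters; ``items="word"``
    over whitespace tokens.  No sentinel padding is used, so strings
    shorter than q have an empty profile.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if items == "char":
        seq: list[str] | str = s
    elif items == "word":
        seq = s.split()
    else:
        raise ValueError(f"unknown q-gram item type: {items!r}")
    grams = Counter(
        tuple(seq[i:i + q]) if items == "word" else seq[i:i + q]
        for i in range(len(seq) - q + 1)
    )
    return QGramProfile(grams=grams, q=q)


def qgram_similarity(
    s1: str,
    s2: str,
    q: int = 3,
    items: str = "char",
    symmetrize: str | None = None,
) -> float:
    """Shared q-grams of s2 relative to the possible q-grams of s1.

    Matches are counted by multiset intersection (each gram occurrence can
    match at most once).  Returns 0 with a logged warning when the reference
    profile is empty (string shorter than q).
    """
    if symmetrize not in (None, "mean"):
        raise ValueError(f"unknown symmetrize mode: {symmetrize!r}")
    if symmetrize == "mean":
        return 0.5 * (
            qgram_similarity(s1, s2, q, items)
            + qgram_similarity(s2, s1, q, items)
        )
    p1 = qgram_profile(s1, q, items)
    p2 = qgram_profile(s2, q, items)
    if p1.size == 0:
        logger.warning(
            "qgram_similarity: reference string shorter than q=%d; returning 0", q
        )
        return 0.0
    matches = sum((p1.grams & p2.grams).values())
    return matches / p1.size


# --------------------------------------------------------------------------
# sentence-level convenience scorers (preprocessing included)
# --------------------------------------------------------------------------

def sentence_jaccard(
    sentence1: str, sentence2: str, config: PreprocessConfig | None = None
) -> float:
    """Jaccard index of two raw sentences after standard preprocessing."""
    t1 = preprocess_sentence(sentence1, config).tokens
    t2 = preprocess_sentence(sentence2, config).tokens
    return jaccard_similarity(t1, t2)


def sentence_qgram(
    sentence1: str,
    sentence2: str,
    q: int = 3,
    config: PreprocessConfig | None = None,
    symmetrize: str | None = None,
) -> float:
    """Q-gram similarity of two raw sentences after standard preprocessing.

    The stripped token sequences are re-joined with single spaces before
    gram extraction, so stopword removal precedes the string metric.
    """
    s1 = " ".join(preprocess_sentence(sentence1, config).tokens)
    s2 = " ".join(preprocess_sentence(sentence2, config).tokens)
    return qgram_similarity(s1, s2, q=q, symmetrize=symmetrize)
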