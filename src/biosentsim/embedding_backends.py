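"""Embedding providers, pooling and cosine scoring.

Two provider contracts exist, mirroring the two families of sentence
representation used for similarity scoring:

* :class:`WordVectorTable` — a per-token vector lookup.  Sentence vectors
  are derived by element-wise max / min / sum / mean ("average") pooling
  across the vectors of the sentence's in-vocabulary tokens.
* :class:`SentenceEncoder` — a whole-sentence encoder (paragraph-vector,
  sent2vec or RNN-style models plug in here via the adapter contract; the
  package never retrains them).

The in-repo trainer, :func:`train_word_table`, builds distributional word
vectors from a sentence-per-line corpus by factorising the positive
pointwise-mutual-information (PPMI) co-occurrence matrix with a truncated
SVD.  Count-based PPMI–SVD vectors are a classical, fully deterministic
stand-alone embedding method whose geometry closely tracks that of
negative-sampling skip-gram, which makes them well suited for a
reproducible desk-scale pipeline; externally trained skip-gram / CBOW /
fastText tables load through :meth:`WordVectorTable.load_word2vec_text`.

Out-of-vocabulary tokens are never silently zero-filled: pooling skips
them and reports their count, and a sentence whose tokens are all OOV
raises :class:`AllTokensOOVError` (surfaced downstream as a missing score).
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "OOVError",
    "AllTokensOOVError",
    "ZeroVectorError",
    "POOLING_STRATEGIES",
    "WordVectorTable",
    "SentenceEncoder",
    "BagOfWordsEncoder",
    "EmbeddingTrainConfig",
    "pool_word_vectors",
    "cosine_similarity",
    "train_word_table",
    "encode_sentence",
    "CosineScorer",
]


class OOVError(KeyError):
    """A token is absent from the embedding vocabulary."""


class AllTokensOOVError(ValueError):
    """Every token of a sentence is out of vocabulary; no vector exists."""


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for the all-zero vector."""


#: Closed set of pooling strategies; "average" is accepted as an alias of
#: "mean" to match common usage.
POOLING_STRATEGIES: tuple[str, ...] = ("max", "min", "sum", "mean")

_POOL_FUNCS = {
    "max": lambda m: m.max(axis=0),
    "min": lambda m: m.min(axis=0),
    "sum": lambda m: m.sum(axis=0),
    "mean": lambda m: m.mean(axis=0),
}


def _canonical_pooling(strategy: str) -> str:
    name = "mean" if strategy == "average" else strategy
    if name not in POOLING_STRATEGIES:
        raise ValueError(
            f"unknown pooling strategy {strategy!r}; choose from "
            f"{POOLING_STRATEGIES} (or 'average')"
        )
    return name


def pool_word_vectors(
    vectors: Sequence[np.ndarray] | np.ndarray, strategy: str = "max"
) -> np.ndarray:
    """Element-wise max / min / sum / mean across a list of word vectors."""
    name = _canonical_pooling(strategy)
    if len(vectors) == 0:
        raise AllTokensOOVError("no in-vocabulary tokens: nothing to pool")
    dims = {len(v) for v in vectors}
    if len(dims) != 1:
        raise ValueError(f"mixed vector lengths {sorted(dims)}; cannot pool")
    matrix = np.asarray(vectors, dtype=float)
    return _POOL_FUNCS[name](matrix)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(θ) = (u·v) / (‖u‖‖v‖); symmetric and scale-invariant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("undefined cosine: zero vector")
    return float(np.dot(u, v) / (nu * nv))


# --------------------------------------------------------------------------
# providers
# --------------------------------------------------------------------------

@runtime_checkable
class SentenceEncoder(Protocol):
    """Whole-sentence encoder contract (adapter for external models)."""

    dimension: int
    provenance: str

    def encode(self, tokens: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


class WordVectorTable:
    """Immutable token → vector lookup of a fixed dimension."""

    def __init__(
        self,
        tokens: Sequence[str],
        matrix: np.ndarray,
        provenance: dict | None = None,
    ) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
            raise ValueError("matrix must be (n_tokens, dimension)")
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self._index = {t: i for i, t in enumerate(tokens)}
        self._matrix = matrix
        self.provenance = dict(provenance or {})

    @property
    def dimension(self) -> int:
        return self._matrix.shape[1]

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self._index)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray:
        try:
            return self._matrix[self._index[token]]
        except KeyError:
            raise OOVError(f"token {token!r} not in vocabulary") from None

    # -- word2vec text format I/O -----------------------------------------

    def save_word2vec_text(self, path: str | Path) -> Path:
        """Write the standard text vector format: a "vocab dim" header line,
        then one token and its whitespace-separated floats per line."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self)} {self.dimension}\n")
            for tok, i in self._index.items():
                vals = " ".join(repr(float(x)) for x in self._matrix[i])
                fh.write(f"{tok} {vals}\n")
        return path

    @classmethod
    def load_word2vec_text(cls, path: str | Path) -> "WordVectorTable":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec header")
            n, dim = int(header[0]), int(header[1])
            tokens: list[str] = []
            rows = np.empty((n, dim), dtype=float)
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"{path}: bad row {i + 2}")
                tokens.append(parts[0])
                rows[i] = [float(x) for x in parts[1:]]
        if len(tokens) != n:
            raise ValueError(f"{path}: header promises {n} rows, found {len(tokens)}")
        return cls(tokens, rows, provenance={"source": str(path)})


class BagOfWordsEncoder:
    """One-hot token-count sentence encoder over a fixed vocabulary.

    The simplest lexical-overlap encoder: a sentence's vector is its token
    count profile, so cosine between two sentences measures pure word
    overlap.  Used as the reference model in contradiction probing, where
    its blindness to negation and antonymy is exactly the phenomenon under
    study.  Unknown tokens are ignored.
    """

    provenance = "bag-of-words one-hot count encoder"

    def __init__(self, vocabulary: Iterable[str]) -> None:
        vocab = sorted(set(vocabulary))
        if not vocab:
            raise ValueError("empty vocabulary")
        self._index = {t: i for i, t in enumerate(vocab)}

    @classmethod
    def from_sentences(cls, token_lists: Iterable[Sequence[str]]) -> "BagOfWordsEncoder":
        return cls(t for toks in token_lists for t in toks)

    @property
    def dimension(self) -> int:
        return len(self._index)

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        vec = np.zeros(self.dimension)
        known = 0
        for t in tokens:
            i = self._index.get(t)
            if i is not None:
                vec[i] += 1.0
                known += 1
        if known == 0:
            raise AllTokensOOVError("all tokens outside encoder vocabulary")
        return vec


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingTrainConfig:
    """Configuration surface of the word-vector trainer.

    ``algorithm`` names the embedding family; ``"ppmi-svd"`` is the in-repo
    trainer, while skip-gram / CBOW / sent2vec-like / PV-DM / PV-DBOW name
    externally trained models loaded through the adapters (the fields are
    still recorded in provenance so configurations stay comparable).
    ``min_count`` excludes rare tokens from the vocabulary — raising it from
    one to five is a standard speed/quality trade-off on large corpora.
    ``epochs`` and ``word_ngrams`` are pass-through surface for iterative
    trainers; the SVD factorisation is single-shot and ignores them.
    """

    algorithm: str = "ppmi-svd"
    dimension: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 5
    word_ngrams: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _cooccurrence(
    lines: Iterable[Sequence[str]], index: dict[str, int], window: int
) -> np.ndarray:
    n = len(index)
    counts = np.zeros((n, n), dtype=float)
    for toks in lines:
        ids = [index[t] for t in toks if t in index]
        for pos, i in enumerate(ids):
            lo = max(0, pos - window)
            for j in ids[lo:pos]:
                counts[i, j] += 1.0
                counts[j, i] += 1.0
    return counts


def train_word_table(
    corpus: str | Path, config: EmbeddingTrainConfig | None = None
) -> WordVectorTable:
    """Train PPMI–SVD word vectors on a sentence-per-line corpus file.

    Tokens occurring fewer than ``min_count`` times are excluded from the
    vocabulary.  Co-occurrence is counted within a symmetric window of
    ``window`` tokens; the PPMI transform max(0, log(p_ij / (p_i p_j))) is
    applied, and the left singular vectors scaled by sqrt of the singular
    values give the word vectors.  Fully deterministic for a fixed corpus
    and config; provenance records the config and its hash.
    """
    config = config or EmbeddingTrainConfig()
    corpus = Path(corpus)
    lines = [ln.split() for ln in corpus.read_text(encoding="utf-8").splitlines()]

    freq = Counter(t for toks in lines for t in toks)
    vocab = sorted(t for t, c in freq.items() if c >= config.min_count)
    if len(vocab) < 2:
        raise ValueError(
            f"corpus too small: effective vocabulary size {len(vocab)} "
            f"(need >= 2 tokens with count >= {config.min_count})"
        )
    index = {t: i for i, t in enumerate(vocab)}

    counts = _cooccurrence(lines, index, config.window)
    total = counts.sum()
    if total == 0:
        raise ValueError("corpus too small: no co-occurrences within window")
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row * row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    dim = min(config.dimension, len(vocab))
    # dense SVD: deterministic and cheap at desk-scale vocabulary sizes
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    matrix = u[:, :dim] * np.sqrt(s[:dim])

    provenance = {
        "trainer": "ppmi-svd",
        "config": dict(config.__dict__),
        "config_hash": config.config_hash(),
        "corpus": str(corpus),
        "vocab_size": len(vocab),
        "effective_dimension": dim,
    }
    return WordVectorTable(vocab, matrix, provenance=provenance)


# --------------------------------------------------------------------------
# sentence encoding and scoring
# --------------------------------------------------------------------------

def encode_sentence(
    provider: WordVectorTable | SentenceEncoder,
    tokens: Sequence[str],
    pooling: str = "max",
) -> tuple[np.ndarray, int]:
    """Vector for one tokenized sentence, plus its OOV token count.

    Word tables pool over the in-vocabulary token vectors with *pooling*;
    sentence encoders delegate to their own ``encode`` (pooling ignored,
    OOV count 0 unless the encoder raises).  A sentence with no usable
    token raises :class:`AllTokensOOVError`.
    """
    if not tokens:
        raise AllTokensOOVError("empty sentence: nothing to encode")
    if isinstance(provider, WordVectorTable):
        known = [provider.vector(t) for t in tokens if t in provider]
        oov = len(tokens) - len(known)
        if not known:
            raise AllTokensOOVError(
                f"all {len(tokens)} tokens out of vocabulary"
            )
        return pool_word_vectors(known, pooling), oov
    return np.asarray(provider.encode(tokens), dtype=float), 0


@dataclass
class CosineScorer:
    """Callable pair scorer: cosine of pooled/encoded sentence vectors.

    ``preprocess`` maps a raw sentence string to tokens; by default the
    standard pipeline from :mod:`biosentsim.corpus_prep` is used.  Raises
    :class:`AllTokensOOVError` / :class:`ZeroVectorError` on unscorable
    pairs, which the evaluation layer records as missing scores.
    """

    provider: WordVectorTable | SentenceEncoder
    pooling: str = "max"
    name: str = "cosine"
    preprocess: "callable | None" = None
    oov_tokens_seen: int = field(default=0, init=False)

    def _tokens(self, sentence: str) -> Sequence[str]:
        if self.preprocess is not None:
            return self.preprocess(sentence)
        from .corpus_prep import preprocess_sentence

        return preprocess_sentence(sentence).tokens

    def __call__(self, sentence1: str, sentence2: str) -> float:
        v1, oov1 = encode_sentence(self.provider, self._tokens(sentence1), self.pooling)
        v2, oov2 = encode_sentence(self.provider, self._tokens(sentence2), self.pooling)
        self.oov_tokens_seen += oov1 + oov2
        return cosine_similarity(v1, v2)
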