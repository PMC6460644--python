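"""Benchmark I/O, correlation evaluation and the contradiction probe.

A benchmark is a tab-separated file of sentence pairs with human gold
similarity scores on a continuous 0–4 scale (0 = no relation, 4 =
semantically equivalent; each pair's score is the mean of several expert
ratings).  Any scorer — string metric, pooled-cosine model, fitted
combiner — is evaluated by Pearson's r and Spearman's r_s between its
per-pair scores and the gold scores.  Reports headline Pearson's r, with
Spearman retained alongside in the JSON.

The contradiction probe compares mean cosine similarity on three subsets:
pairs rated highly similar by humans (gold >= 3.5), negation pairs (the
second sentence is the first with a negation inserted), and antonym pairs
(one keyword swapped for its antonym).  A model that understood
contradiction would score the high-similarity subset above the other two;
lexical-overlap-driven models do the opposite, because negated and
antonym-swapped sentences share almost all of their tokens with the
original.  No significance testing is performed — the subsets (of the
order of 7–13 pairs) are far too small for a meaningful test.
"""

from __future__ import annotations

import csv
import json
import logging
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "BenchmarkPair",
    "EvaluationReport",
    "ContradictionReport",
    "read_benchmark",
    "write_benchmark",
    "pearson",
    "spearman",
    "evaluate_scorer",
    "select_high_similarity_subset",
    "contradiction_probe",
]

logger = logging.getLogger(__name__)

SUBSET_LABELS = ("main", "negation", "antonym", "high_similarity")

#: Pair scorer contract: (sentence1, sentence2) -> similarity score.
PairScorer = Callable[[str, str], float]


@dataclass(frozen=True)
class BenchmarkPair:
    """One benchmark row: two sentences plus an optional gold score."""

    pair_id: str
    sentence1: str
    sentence2: str
    gold: float | None = None
    subset: str | None = None

    def __post_init__(self) -> None:
        if not self.sentence1 or not self.sentence2:
            raise ValueError(f"pair {self.pair_id}: empty sentence")
        if self.gold is not None and not 0.0 <= self.gold <= 4.0:
            raise ValueError(
                f"pair {self.pair_id}: gold {self.gold} outside [0, 4]"
            )


_COLUMNS = ("pair_id", "sentence1", "sentence2", "score", "subset")


def read_benchmark(path: str | Path) -> list[BenchmarkPair]:
    """Read the tab-separated benchmark dialect.

    Columns: pair_id, sentence1, sentence2, score, subset — header row
    required; score and subset may be empty.  Malformed rows and
    out-of-range gold scores raise with the offending row number.
    """
    path = Path(path)
    pairs: list[BenchmarkPair] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header[:3]) != _COLUMNS[:3]:
            raise ValueError(f"{path}: missing or unrecognised header row")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: malformed row {lineno}: {row!r}")
            pair_id, s1, s2 = row[0], row[1], row[2]
            gold_str = row[3] if len(row) > 3 else ""
            subset = row[4] if len(row) > 4 and row[4] else None
            try:
                gold = float(gold_str) if gold_str != "" else None
            except ValueError:
                raise ValueError(
                    f"{path}: row {lineno}: unparseable score {gold_str!r}"
                ) from None
            try:
                pairs.append(
                    BenchmarkPair(pair_id, s1, s2, gold=gold, subset=subset)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from None
    return pairs


def write_benchmark(pairs: Sequence[BenchmarkPair], path: str | Path) -> Path:
    """Write pairs in the benchmark TSV dialect (lossless round-trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for p in pairs:
            writer.writerow(
                [
                    p.pair_id,
                    p.sentence1,
                    p.sentence2,
                    "" if p.gold is None else repr(p.gold),
                    p.subset or "",
                ]
            )
    return path


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def _check_corr_args(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(xa) < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise ValueError("undefined correlation: zero variance input")
    return xa, ya


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient r."""
    xa, ya = _check_corr_args(x, y)
    return float(stats.pearsonr(xa, ya).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation r_s (Pearson on mid-ranks; ties get average rank)."""
    xa, ya = _check_corr_args(x, y)
    return float(stats.spearmanr(xa, ya).statistic)


# --------------------------------------------------------------------------
# scorer evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    """Per-metric predicted scores and their correlation with gold."""

    metric_name: str
    n_pairs: int
    predicted: dict[str, float]
    pearson_r: float
    spearman_rs: float
    n_missing: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "metric_name": self.metric_name,
                "n_pairs": self.n_pairs,
                "pearson_r": self.pearson_r,
                "spearman_rs": self.spearman_rs,
                "n_missing": self.n_missing,
                "predicted": self.predicted,
            },
            indent=2,
        )

    def summary(self) -> str:
        return (
            f"{self.metric_name}: r = {self.pearson_r:.3f}, "
            f"r_s = {self.spearman_rs:.3f} "
            f"(n = {self.n_pairs}, missing = {self.n_missing})"
        )


def evaluate_scorer(
    scorer: PairScorer,
    benchmark: Sequence[BenchmarkPair],
    metric_name: str = "scorer",
    max_missing_fraction: float = 0.5,
) -> EvaluationReport:
    """Score every pair and correlate predictions with gold scores.

    Pairs the scorer cannot handle (all tokens out of vocabulary, zero
    vectors) are excluded from the correlation and counted in
    ``n_missing`` — never imputed.  More than *max_missing_fraction*
    missing raises, since the correlation would be meaningless.
    """
    with_gold = [p for p in benchmark if p.gold is not None]
    if not with_gold:
        raise ValueError("benchmark has no gold scores")
    predicted: dict[str, float] = {}
    missing: list[str] = []
    for p in with_gold:
        try:
            predicted[p.pair_id] = float(scorer(p.sentence1, p.sentence2))
        except (ValueError, KeyError) as exc:
            logger.warning("pair %s unscorable: %s", p.pair_id, exc)
            missing.append(p.pair_id)
    if len(missing) > max_missing_fraction * len(with_gold):
        raise ValueError(
            f"{len(missing)}/{len(with_gold)} pairs unscorable; "
            "report would be meaningless"
        )
    scored = [p for p in with_gold if p.pair_id in predicted]
    gold = [p.gold for p in scored]
    pred = [predicted[p.pair_id] for p in scored]
    return EvaluationReport(
        metric_name=metric_name,
        n_pairs=len(scored),
        predicted=predicted,
        pearson_r=pearson(pred, gold),
        spearman_rs=spearman(pred, gold),
        n_missing=len(missing),
    )


# --------------------------------------------------------------------------
# contradiction probe
# --------------------------------------------------------------------------

def select_high_similarity_subset(
    benchmark: Sequence[BenchmarkPair], threshold: float = 3.5
) -> list[BenchmarkPair]:
    """Pairs rated highly similar by the annotators: gold >= threshold
    (inclusive), order preserved."""
    return [p for p in benchmark if p.gold is not None and p.gold >= threshold]


@dataclass(frozen=True)
class ContradictionReport:
    """Mean similarity per subset for each probed model.

    ``subset_means``: model name → {subset label → mean score}.
    ``subset_sizes``: subset label → number of pairs actually scored.
    ``ordering_flag``: model name → True when the model orders the subsets
    as a contradiction-aware system should (high-similarity mean strictly
    above both the negation and the antonym mean).
    """

    subset_means: dict[str, dict[str, float]]
    subset_sizes: dict[str, dict[str, int]]
    ordering_flag: dict[str, bool]
    n_skipped: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subset_means": self.subset_means,
                "subset_sizes": self.subset_sizes,
                "ordering_flag": self.ordering_flag,
                "n_skipped": self.n_skipped,
            },
            indent=2,
        )

    def table(self) -> str:
        """Human-readable per-model table of subset means."""
        labels = sorted({s for m in self.subset_means.values() for s in m})
        width = max(len(m) for m in self.subset_means) + 2
        lines = ["".join([" " * width] + [f"{s:>18}" for s in labels])]
        for model, means in self.subset_means.items():
            cells = [
                f"{means[s]:>18.3f}" if s in means else " " * 18 for s in labels
            ]
            lines.append(f"{model:<{width}}" + "".join(cells))
        return "\n".join(lines)


def contradiction_probe(
    scorers: Mapping[str, PairScorer],
    subsets: Mapping[str, Sequence[BenchmarkPair]],
) -> ContradictionReport:
    """Mean pair similarity per subset for each scorer.

    Each subset must be nonempty.  Pairs a scorer fails on are skipped and
    counted; the subset mean is taken over the remainder.  No significance
    test is run on the means.
    """
    for label, pairs in subsets.items():
        if not pairs:
            raise ValueError(f"subset {label!r} is empty")
    means: dict[str, dict[str, float]] = {}
    sizes: dict[str, dict[str, int]] = {}
    skipped: dict[str, int] = {}
    flags: dict[str, bool] = {}
    for name, scorer in scorers.items():
        means[name] = {}
        sizes[name] = {}
        skipped[name] = 0
        for label, pairs in subsets.items():
            scores: list[float] = []
            for p in pairs:
                try:
                    scores.append(float(scorer(p.sentence1, p.sentence2)))
                except (ValueError, KeyError) as exc:
                    logger.warning(
                        "probe %s/%s: pair %s skipped: %s", name, label, p.pair_id, exc
                    )
                    skipped[name] += 1
            if not scores:
                raise ValueError(f"scorer {name!r} failed on all of {label!r}")
            means[name][label] = float(np.mean(scores))
            sizes[name][label] = len(scores)
        m = means[name]
        if {"high_similarity", "negation", "antonym"} <= set(m):
            flags[name] = (
                m["high_similarity"] > m["negation"]
                and m["high_similarity"] > m["antonym"]
            )
        else:
            flags[name] = False
    return ContradictionReport(
        subset_means=means,
        subset_sizes=sizes,
        ordering_flag=flags,
        n_skipped=skipped,
    )
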