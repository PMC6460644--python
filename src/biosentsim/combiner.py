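"""Combine per-pair similarity scores into a single estimate.

Two combiners are provided.  The *unsupervised hybrid* simply averages the
scores of several metrics for a pair.  The *supervised* combiner fits an
ordinary-least-squares linear regression

    y = b_0 + Σ_j b_j x_j

of the human gold score y on the per-metric scores x_j, with no
regularisation.  Because a benchmark of ~100 pairs leaves the in-sample
versus held-out distinction genuinely consequential, both an in-sample fit
and seeded k-fold cross-validated predictions are exposed and always
labelled as such.

Two named feature presets mirror the standard configurations: the hybrid
mean over {jaccard, qgram, pv_dbow_cosine, sent2vec_cosine}, and the
supervised regression over {jaccard, qgram, sent2vec_cosine, pv_dm_cosine,
skipthoughts_cosine, fasttext_cosine}.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FeatureVector",
    "LinearCombiner",
    "FEATURE_PRESETS",
    "unsupervised_mean",
    "fit_linear_combiner",
    "predict",
    "cross_validated_predictions",
]

FEATURE_PRESETS: dict[str, tuple[str, ...]] = {
    "hybrid": ("jaccard", "qgram", "pv_dbow_cosine", "sent2vec_cosine"),
    "supervised": (
        "jaccard",
        "qgram",
        "sent2vec_cosine",
        "pv_dm_cosine",
        "skipthoughts_cosine",
        "fasttext_cosine",
    ),
}


@dataclass(frozen=True)
class FeatureVector:
    """Ordered map of metric name → similarity score for one sentence pair."""

    pair_id: str
    features: dict[str, float]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError(f"pair {self.pair_id}: empty feature map")
        bad = [k for k, v in self.features.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"pair {self.pair_id}: non-finite features {bad}")

    @property
    def k(self) -> int:
        return len(self.features)

    def as_array(self, feature_order: Sequence[str]) -> np.ndarray:
        missing = [n for n in feature_order if n not in self.features]
        extra = [n for n in self.features if n not in feature_order]
        if missing or extra:
            raise ValueError(
                f"pair {self.pair_id}: feature mismatch "
                f"(missing {missing}, extra {extra})"
            )
        return np.array([self.features[n] for n in feature_order], dtype=float)


def unsupervised_mean(features: FeatureVector | Mapping[str, float]) -> float:
    """Arithmetic mean of the per-metric scores (the hybrid combiner)."""
    values = (
        features.features if isinstance(features, FeatureVector) else dict(features)
    )
    if not values:
        raise ValueError("cannot average an empty feature map")
    return float(np.mean(list(values.values())))


@dataclass(frozen=True)
class LinearCombiner:
    """Fitted OLS model: intercept b_0 and per-metric coefficients b_j."""

    intercept: float
    coefficients: dict[str, float]
    feature_order: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.feature_order):
            raise ValueError("coefficients must cover exactly feature_order")

    def predict(self, features: FeatureVector, clip: bool = False) -> float:
        x = features.as_array(self.feature_order)
        b = np.array([self.coefficients[n] for n in self.feature_order])
        y = float(self.intercept + x @ b)
        return float(np.clip(y, 0.0, 4.0)) if clip else y

    # -- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "feature_order": list(self.feature_order),
                "metadata": self.metadata,
            },
            indent=2,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json(), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, text: str) -> "LinearCombiner":
        d = json.loads(text)
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            feature_order=tuple(d["feature_order"]),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LinearCombiner":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _design_matrix(
    rows: Sequence[tuple[FeatureVector, float]], feature_order: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack(
        [np.ones(len(rows))]
        + [
            np.array([fv.features[n] for fv, _ in rows], dtype=float)
            for n in feature_order
        ]
    )
    y = np.array([gold for _, gold in rows], dtype=float)
    return X, y


def _collinear_features(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of feature columns involved in a rank deficiency."""
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps
    null_mask = s <= tol
    involved: set[str] = set()
    for v in vt[null_mask]:
        for j, w in enumerate(v[1:]):  # skip intercept column
            if abs(w) > 1e-8:
                involved.add(names[j])
    return sorted(involved)


def fit_linear_combiner(
    rows: Sequence[tuple[FeatureVector, float]],
    feature_order: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> LinearCombiner:
    """Ordinary least squares fit of gold scores on similarity features.

    Requires at least k + 2 rows for k features, a non-constant gold
    column, and a full-rank design (an informative error names the
    collinear features otherwise).  Residuals of the returned fit are
    orthogonal to every feature column (the normal equations).
    """
    if not rows:
        raise ValueError("no training rows")
    if feature_order is None:
        feature_order = tuple(rows[0][0].features)
    k = len(feature_order)
    if len(rows) < k + 2:
        raise ValueError(f"need >= {k + 2} rows to fit {k} features, got {len(rows)}")
    for fv, _ in rows:
        fv.as_array(feature_order)  # validates consistent feature sets

    X, y = _design_matrix(rows, feature_order)
    if np.ptp(y) == 0.0:
        raise ValueError("degenerate gold column: all values identical")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_features(X, list(feature_order))
        raise ValueError(f"rank-deficient design; collinear features: {bad}")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    meta = {"n": len(rows), **(metadata or {})}
    return LinearCombiner(
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(feature_order, beta[1:])},
        feature_order=tuple(feature_order),
        metadata=meta,
    )


def predict(
    model: LinearCombiner, features: FeatureVector, clip: bool = False
) -> float:
    """Apply a fitted combiner to one feature vector (module-level alias)."""
    return model.predict(features, clip=clip)


def cross_validated_predictions(
    rows: Sequence[tuple[FeatureVector, float]],
    n_folds: int = 10,
    seed: int = 0,
    feature_order: Sequence[str] | None = None,
) -> dict[str, float]:
    """Out-of-fold predictions from seeded k-fold cross-validation.

    Each pair's prediction comes from a combiner fitted on the other
    folds, so the returned scores are honest held-out estimates.  Returns
    pair_id → predicted score.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if feature_order is None:
        feature_order = tuple(rows[0][0].features)
    n = len(rows)
    if n < n_folds:
        raise ValueError(f"{n} rows cannot be split into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    preds: dict[str, float] = {}
    for fold in folds:
        test = set(int(i) for i in fold)
        train = [rows[i] for i in range(n) if i not in test]
        model = fit_linear_combiner(train, feature_order=feature_order)
        for i in test:
            fv, _ = rows[i]
            preds[fv.pair_id] = model.predict(fv)
    return preds
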