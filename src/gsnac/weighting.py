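"""Feature scaling and importance weighting, fitted on training folds only.

Numeric features are min-max normalized into [0, 1] so that the distance
computation is not dominated by features with large units; the structure of
variation within a feature is preserved (unlike standardization). Feature
importance is the one-way ANOVA F statistic of each feature against the class
label; the F scores, normalized to sum to one, become the weight vector *w*
of the hybrid distance.

Fitting is strictly train-only: :class:`NormalizationParams` and
:class:`FeatureWeightVector` never see test rows, and test values outside the
training range are clipped into [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

from .dataio import CATEGORICAL, NUMERIC, TabularDataset

__all__ = [
    "NormalizationParams",
    "FeatureWeightVector",
    "fit_normalizer",
    "apply_normalizer",
    "anova_f_scores",
    "feature_weights",
]

#: Finite stand-in for an infinite F statistic (a feature that separates the
#: classes with zero within-class variance); keeps weight normalization finite.
F_SENTINEL = 1e12


@dataclass(frozen=True)
class NormalizationParams:
    """Per-numeric-feature training (min, max), in feature units."""

    bounds: dict[str, tuple[float, float]]

    @property
    def degenerate(self) -> tuple[str, ...]:
        """Features constant on the training data (max == min)."""
        return tuple(f for f, (lo, hi) in self.bounds.items() if hi == lo)


@dataclass(frozen=True)
class FeatureWeightVector:
    """Non-negative per-feature importance weights summing to one.

    Carries the retained feature names and their kinds so the similarity
    module can route each weight to the L2 (numeric) or L0 (categorical)
    part of the hybrid distance.
    """

    feature_names: tuple[str, ...]
    kinds: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.feature_names) != len(self.kinds) or len(self.kinds) != w.size:
            raise ValueError("names, kinds and weights must align")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    def _of_kind(self, kind: str) -> tuple[tuple[str, ...], np.ndarray]:
        idx = [i for i, k in enumerate(self.kinds) if k == kind]
        return tuple(self.feature_names[i] for i in idx), self.weights[idx]

    @property
    def numeric(self) -> tuple[tuple[str, ...], np.ndarray]:
        return self._of_kind(NUMERIC)

    @property
    def categorical(self) -> tuple[tuple[str, ...], np.ndarray]:
        return self._of_kind(CATEGORICAL)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "feature_names": list(self.feature_names),
            "kinds": list(self.kinds),
            "weights": self.weights.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureWeightVector":
        raw = json.loads(Path(path).read_text())
        return cls(tuple(raw["feature_names"]), tuple(raw["kinds"]),
                   np.asarray(raw["weights"], dtype=float))


def fit_normalizer(train: TabularDataset) -> NormalizationParams:
    """Record each numeric feature's training minimum and maximum."""
    if train.X.isna().any().any():
        raise ValueError("fit_normalizer requires cleaned data")
    bounds = {
        col: (float(train.X[col].min()), float(train.X[col].max()))
        for col in train.numeric
    }
    return NormalizationParams(bounds=bounds)


def apply_normalizer(ds: TabularDataset, params: NormalizationParams) -> TabularDataset:
    """Linearly map numeric cells into [0, 1] with the fitted bounds.

    A feature constant at fit time maps to 0 everywhere; test values outside
    the training range clip to the nearest endpoint. Categorical columns are
    untouched.
    """
    if set(params.bounds) != set(ds.numeric):
        raise ValueError(
            f"normalizer features {sorted(params.bounds)} do not match "
            f"dataset numeric features {sorted(ds.numeric)}"
        )
    X = ds.X.copy()
    for col, (lo, hi) in params.bounds.items():
        if hi == lo:
            X[col] = 0.0
        else:
            X[col] = ((X[col] - lo) / (hi - lo)).clip(0.0, 1.0)
    return replace(ds, X=X)


def anova_f_scores(train: TabularDataset) -> pd.Series:
    """One-way ANOVA F statistic of each feature against the class label.

    F = (SS_between / (c-1)) / (SS_within / (n-c)). A feature constant across
    all samples scores 0; a feature with zero within-class variance but
    distinct class means scores the finite sentinel ``F_SENTINEL``.
    Categorical features are scored on their integer codes.
    """
    y = train.require_labels()
    if y.nunique() < 2:
        raise ValueError("ANOVA requires at least 2 classes")
    X = train.X.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # f_classif warns about constant features; they score 0 by design
        warnings.simplefilter("ignore", UserWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            f, _ = f_classif(X, y.to_numpy())
    f = np.asarray(f, dtype=float)
    f[np.isnan(f)] = 0.0
    f[np.isinf(f)] = F_SENTINEL
    f[f < 0] = 0.0
    return pd.Series(f, index=train.X.columns, name="anova_f")


def feature_weights(
    scores: pd.Series,
    kinds: tuple[str, ...] | None = None,
    top_m: int | None = None,
) -> FeatureWeightVector:
    """Turn importance scores into a normalized weight vector.

    Optionally keep only the ``top_m`` highest-scoring features (the usual
    practice on very wide genomic tables); the retained scores are rescaled
    to sum to one. All-zero retained scores degrade to uniform weights.

    ``kinds`` gives the per-feature kind aligned with ``scores``; numeric is
    assumed when omitted.
    """
    if kinds is None:
        kinds = (NUMERIC,) * len(scores)
    if len(kinds) != len(scores):
        raise ValueError("kinds must align with scores")
    order = sorted(range(len(scores)), key=lambda i: (-scores.iloc[i], scores.index[i]))
    if top_m is not None:
        if not 1 <= top_m <= len(scores):
            raise ValueError(f"top_m must be in [1, {len(scores)}]")
        keep = sorted(order[:top_m])
    else:
        keep = list(range(len(scores)))
    vals = scores.iloc[keep].to_numpy(dtype=float)
    total = vals.sum()
    w = vals / total if total > 0 else np.full(len(keep), 1.0 / len(keep))
    return FeatureWeightVector(
        feature_names=tuple(scores.index[keep]),
        kinds=tuple(kinds[i] for i in keep),
        weights=w,
    )
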