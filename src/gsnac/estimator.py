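"""Scikit-learn-style estimator wrapping the full pipeline.

``GSNAcClassifier`` composes the library modules end to end: labelization
and min-max normalization fitted on the training rows, ANOVA-F feature
weights, the hybrid weighted distance matrix, the similarity graph, top-k
edge pruning, class fortification, and the two-phase margin-gated
prediction. It follows the scikit-learn estimator contract (``get_params``
/ ``set_params``, clone-compatible ``__init__``, fitted attributes with a
trailing underscore) and therefore drops into sklearn pipelines and model
selection, with the caveat that categorical columns may carry string
tokens, so input validation is deliberately permissive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataio import TabularDataset, labelize
from .graphmodel import PruningPolicy, build_raw_graph, choose_k, fortify_edges, prune_edges
from .predict import FittedModel, PredictionTrace, predict_batch
from .similarity import distances_to_similarities, pairwise_distances
from .weighting import anova_f_scores, apply_normalizer, feature_weights, fit_normalizer

__all__ = ["GSNAcClassifier"]


class GSNAcClassifier(ClassifierMixin, BaseEstimator):
    """Graph-based classifier with a visual, traceable decision process.

    Parameters
    ----------
    categorical_features : sequence of column names or int positions, optional
        Columns holding category tokens (L0 mismatch metric); all others
        are numeric (weighted Euclidean).
    k_max : int, default 10
        Upper limit on the per-node edge budget; the effective k is
        ``min(k_max, least-represented class count)`` per training set.
    alpha : float, default 0.5
        Fortification factor: same-class edge weights scale by ``1 + alpha``,
        cross-class by ``1 - alpha``. Must lie in [0, 1).
    margin_threshold : float, default 0.01
        Minimum phase-1 margin between the top two class scores for the
        vectorial vote to stand; below it the topological fallback decides.
    margin_mode : {"relative", "absolute"}, default "relative"
        Relative margin is ``(s1 - s2)/s1``; absolute is ``s1 - s2``.
    top_m : int, optional
        Keep only the ``top_m`` best-scoring features (for very wide data);
        by default all features are kept and weighted.

    Attributes
    ----------
    classes_ : ndarray of unique class tokens (sorted).
    model_ : :class:`gsnac.predict.FittedModel` with the frozen GCM,
        weights, normalizer, encoding and training max distance.
    gcm_ : networkx.Graph — the pruned, fortified graph classifier model.
    weights_, normalizer_, encoding_, max_train_distance_, k_effective_ :
        the individual fitted components.
    """

    def __init__(
        self,
        categorical_features=None,
        k_max: int = 10,
        alpha: float = 0.5,
        margin_threshold: float = 0.01,
        margin_mode: str = "relative",
        top_m: int | None = None,
    ):
        self.categorical_features = categorical_features
        self.k_max = k_max
        self.alpha = alpha
        self.margin_threshold = margin_threshold
        self.margin_mode = margin_mode
        self.top_m = top_m

    # -- input marshalling ------------------------------------------------
    def _as_dataset(self, X, y=None, prefix: str = "s") -> TabularDataset:
        if isinstance(X, TabularDataset):
            if y is not None and X.y is None:
                raise ValueError("pass labels inside the TabularDataset")
            return X
        if isinstance(X, pd.DataFrame):
            frame = X.copy()
            if frame.index.is_unique:
                frame.index = frame.index.map(str)
            else:
                frame.index = [f"{prefix}{i}" for i in range(len(frame))]
        else:
            arr = np.asarray(X)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            frame = pd.DataFrame(
                arr,
                columns=[f"x{j}" for j in range(arr.shape[1])],
                index=[f"{prefix}{i}" for i in range(arr.shape[0])],
            )
        cats = self._resolve_categorical(frame.columns)
        for col in frame.columns:
            if col not in cats:
                frame[col] = pd.to_numeric(frame[col])
        ys = None
        if y is not None:
            ys = pd.Series(np.asarray(y), index=frame.index, name="class")
        return TabularDataset(X=frame, y=ys, categorical=cats)

    def _resolve_categorical(self, columns) -> tuple:
        if not self.categorical_features:
            return ()
        cats = []
        for c in self.categorical_features:
            if isinstance(c, (int, np.integer)):
                cats.append(columns[c])
            elif c in columns:
                cats.append(c)
            else:
                raise ValueError(f"unknown categorical feature {c!r}")
        return tuple(cats)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y=None):
        """Learn transforms, weights and the GCM from the training data."""
        ds = self._as_dataset(X, y, prefix="s")
        ds.validate_training()

        coded, encoding = labelize(ds)
        normalizer = fit_normalizer(coded)
        transformed = apply_normalizer(coded, normalizer)

        scores = anova_f_scores(transformed)
        weights = feature_weights(scores, kinds=transformed.feature_kinds, top_m=self.top_m)

        D = pairwise_distances(transformed, weights)
        A = distances_to_similarities(D)
        labels = transformed.require_labels()
        raw = build_raw_graph(A, classes=labels.tolist(), ids=transformed.sample_ids)

        counts = labels.value_counts().to_dict()
        k_eff = choose_k(counts, self.k_max)
        pruned = prune_edges(raw, PruningPolicy(k_max=self.k_max, k_effective=k_eff))
        gcm = fortify_edges(pruned, self.alpha)

        self.model_ = FittedModel(
            weights=weights,
            normalizer=normalizer,
            encoding=encoding,
            max_train_distance=A.max_train_distance,
            k_effective=k_eff,
            gcm=gcm,
            node_features=transformed.X,
        )
        self.classes_ = np.array(sorted(labels.unique(), key=str))
        self.n_features_in_ = ds.n_features
        self.feature_names_in_ = np.asarray(ds.feature_names, dtype=object)
        self.weights_ = weights
        self.normalizer_ = normalizer
        self.encoding_ = encoding
        self.max_train_distance_ = A.max_train_distance
        self.k_effective_ = k_eff
        self.raw_graph_ = raw
        self.gcm_ = gcm
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("GSNAcClassifier is not fitted yet; call fit first")

    def predict_traces(self, X) -> list[PredictionTrace]:
        """Full per-sample prediction traces (the explainability output)."""
        self._check_fitted()
        ds = self._as_dataset(X, prefix="q")
        if tuple(ds.feature_names) != tuple(self.feature_names_in_):
            raise ValueError(
                f"feature mismatch: fitted on {tuple(self.feature_names_in_)}, "
                f"got {tuple(ds.feature_names)}"
            )
        return predict_batch(
            ds, self.model_, threshold=self.margin_threshold, margin_mode=self.margin_mode
        )

    def predict(self, X):
        """Predicted class token per row of ``X``."""
        traces = self.predict_traces(X)
        return np.asarray([t.predicted_class for t in traces])
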