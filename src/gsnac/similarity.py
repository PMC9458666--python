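"""Hybrid weighted distances between samples and their conversion to
similarities.

The metric combines a weighted Euclidean (L2) part over numeric features with
a weighted mismatch (L0) part over categorical features:

    dist_L2(u, v) = sqrt( sum_i w_i (u_i - v_i)^2 )        numeric dims i
    dist_L0(u, v) = sum_j w_j [u_j != v_j]                 categorical dims j
    dist(u, v)^2  = dist_L2^2 + dist_L0^2

Distances become edge similarities by subtracting from the maximum pairwise
training distance:

    s(u, v) = max(D) - dist(u, v)

so the farthest training pair gets similarity exactly 0, i.e. no edge. The
maximum is stored on the adjacency matrix: at test time the *training*
maximum is reused and more distant test pairs clip to similarity 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dataio import TabularDataset
from .weighting import FeatureWeightVector

__all__ = [
    "DistanceMatrix",
    "AdjacencyMatrix",
    "weighted_l2",
    "weighted_l0",
    "combined_distance",
    "pairwise_distances",
    "distances_to_similarities",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise distances over training samples."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape must match sample ids")
        if (d < 0).any() or not np.allclose(d, d.T) or np.diagonal(d).any():
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "values", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Upper-triangular similarity scores plus the training max distance.

    ``values[i, j]`` for i < j holds s(i, j); the diagonal and lower triangle
    are zero (self-loops removed, symmetric half dropped). An entry equal to
    0 means "no edge".
    """

    sample_ids: tuple[str, ...]
    values: np.ndarray
    max_train_distance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def edges(self):
        """Yield (id_u, id_v, similarity) for every positive entry."""
        iu, ju = np.nonzero(np.triu(self.values, k=1) > 0)
        for i, j in zip(iu, ju):
            yield self.sample_ids[i], self.sample_ids[j], float(self.values[i, j])


def weighted_l2(u, v, w) -> float:
    """Weighted Euclidean distance sqrt(sum w_i (u_i - v_i)^2)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (u.shape == v.shape == w.shape):
        raise ValueError("u, v and w must have equal lengths")
    return float(np.sqrt(np.sum(w * (u - v) ** 2)))


def weighted_l0(u, v, w) -> float:
    """Weighted category mismatch: sum of w_j over dims where u_j != v_j."""
    u = np.asarray(u)
    v = np.asarray(v)
    w = np.asarray(w, dtype=float)
    if not (u.shape == v.shape == w.shape):
        raise ValueError("u, v and w must have equal lengths")
    return float(np.sum(w[u != v]))


def combined_distance(u: pd.Series, v: pd.Series, w: FeatureWeightVector) -> float:
    """Hybrid distance sqrt(L2^2 + L0^2) between two samples.

    ``u`` and ``v`` are feature-indexed rows (normalized numeric cells,
    labelized categorical codes); features are routed by the kinds stored on
    the weight vector.
    """
    num_names, num_w = w.numeric
    cat_names, cat_w = w.categorical
    d2 = weighted_l2(u[list(num_names)], v[list(num_names)], num_w) if num_names else 0.0
    d0 = weighted_l0(u[list(cat_names)], v[list(cat_names)], cat_w) if cat_names else 0.0
    return float(np.sqrt(d2 * d2 + d0 * d0))


def _component_matrices(
    X: pd.DataFrame, Z: pd.DataFrame, w: FeatureWeightVector
) -> np.ndarray:
    """Pairwise hybrid distances between rows of X and rows of Z."""
    num_names, num_w = w.numeric
    cat_names, cat_w = w.categorical
    d2sq = np.zeros((len(X), len(Z)))
    if num_names:
        a = X[list(num_names)].to_numpy(dtype=float) * np.sqrt(num_w)
        b = Z[list(num_names)].to_numpy(dtype=float) * np.sqrt(num_w)
        d2sq = cdist(a, b, metric="sqeuclidean")
    d0 = np.zeros((len(X), len(Z)))
    for name, wj in zip(cat_names, cat_w):
        col_a = X[name].to_numpy()
        col_b = Z[name].to_numpy()
        d0 += wj * (col_a[:, None] != col_b[None, :])
    return np.sqrt(d2sq + d0 * d0)


def pairwise_distances(train: TabularDataset, w: FeatureWeightVector) -> DistanceMatrix:
    """Symmetric matrix of combined distances over all training pairs."""
    if train.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    d = _component_matrices(train.X, train.X, w)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp noise
    return DistanceMatrix(sample_ids=train.sample_ids, values=d)


def cross_distances(tests: TabularDataset, train_like: pd.DataFrame,
                    w: FeatureWeightVector) -> np.ndarray:
    """Hybrid distances from each test row to each reference (GCM) row."""
    return _component_matrices(tests.X, train_like, w)


def distances_to_similarities(D: DistanceMatrix) -> AdjacencyMatrix:
    """Subtract every distance from the matrix maximum; keep the upper half.

    The pair(s) attaining the maximum get similarity exactly 0 and therefore
    no edge; the diagonal (self-loops) and the redundant lower triangle are
    dropped.
    """
    if len(D.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    dmax = float(D.values.max())
    s = dmax - D.values
    s = np.triu(s, k=1)
    return AdjacencyMatrix(sample_ids=D.sample_ids, values=s, max_train_distance=dmax)
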