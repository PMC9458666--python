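"""Tabular dataset container, CSV ingestion, cleaning, labelization and
synthetic fixtures.

A :class:`TabularDataset` is the single in-memory currency of the package: a
pandas DataFrame of feature values indexed by unique sample identifiers, an
optional aligned Series of class tokens, and the set of columns to be treated
as categorical. Categorical cells are mapped to contiguous integer codes
("labelization") rather than one-hot dummies, so the feature count never
changes; the categorical-ness of a column is remembered so that downstream
distance computation can apply a mismatch (L0) metric instead of a Euclidean
one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TabularDataset",
    "DatasetSchema",
    "LabelEncoding",
    "read_dataset",
    "omit_missing",
    "labelize",
    "apply_encoding",
    "make_moons_dataset",
    "make_blobs_dataset",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class TabularDataset:
    """Named samples x typed features, with optional class labels.

    Parameters
    ----------
    X : pandas.DataFrame
        Feature values, one row per sample; the index holds the unique
        sample identifiers.
    y : pandas.Series or None
        Class token per sample, aligned with ``X.index``; ``None`` for
        unlabeled prediction input.
    categorical : tuple of str
        Names of the columns carrying category tokens; every other column is
        numeric.
    """

    X: pd.DataFrame
    y: pd.Series | None = None
    categorical: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.X.shape[1] < 1:
            raise ValueError("dataset must have at least one feature")
        if self.X.index.has_duplicates:
            dupes = self.X.index[self.X.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        unknown = set(self.categorical) - set(self.X.columns)
        if unknown:
            raise ValueError(f"categorical columns not in data: {sorted(unknown)}")
        if self.y is not None and len(self.y) != len(self.X):
            raise ValueError("class labels not aligned with samples")

    # -- convenience views ------------------------------------------------
    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.X.index)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    @property
    def feature_kinds(self) -> tuple[str, ...]:
        cats = set(self.categorical)
        return tuple(CATEGORICAL if c in cats else NUMERIC for c in self.X.columns)

    @property
    def numeric(self) -> tuple[str, ...]:
        cats = set(self.categorical)
        return tuple(c for c in self.X.columns if c not in cats)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_labels(self) -> pd.Series:
        if self.y is None:
            raise ValueError("dataset has no class labels")
        return self.y

    def validate_training(self) -> None:
        """Check the invariants a training set must satisfy."""
        y = self.require_labels()
        if y.isna().any() or self.X.isna().any().any():
            raise ValueError("training data contains missing cells; run omit_missing first")
        if y.nunique() < 2:
            raise ValueError("training data must contain at least 2 distinct classes")

    def subset(self, ids: Sequence) -> "TabularDataset":
        """Row subset by sample id, preserving order of ``ids``."""
        X = self.X.loc[list(ids)]
        y = None if self.y is None else self.y.loc[list(ids)]
        return replace(self, X=X, y=y)


@dataclass(frozen=True)
class DatasetSchema:
    """Column-role declaration for a delimited-text dataset."""

    id_col: str
    class_col: str | None = None
    categorical_cols: tuple[str, ...] = ()
    delimiter: str = ","
    na_tokens: tuple[str, ...] = ("", "NA", "NaN")

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSchema":
        raw = json.loads(Path(path).read_text())
        return cls(
            id_col=raw["id_col"],
            class_col=raw.get("class_col"),
            categorical_cols=tuple(raw.get("categorical_cols", ())),
            delimiter=raw.get("delimiter", ","),
            na_tokens=tuple(raw.get("na_tokens", ("", "NA", "NaN"))),
        )


@dataclass(frozen=True)
class LabelEncoding:
    """Category-token -> integer code maps, one per categorical feature.

    Codes are contiguous from 0 in lexicographic token order, so the
    encoding is deterministic across runs and platforms. ``class_order``
    records the sorted class tokens seen at fit time.
    """

    mapping: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    class_order: tuple = ()

    def decode(self, feature: str, code: int):
        inverse = {v: k for k, v in self.mapping[feature].items()}
        return inverse[code]


def read_dataset(path: str | Path, schema: DatasetSchema) -> TabularDataset:
    """Read a delimited-text dataset according to a column-role schema.

    Cells matching ``schema.na_tokens`` become missing; declared numeric
    columns are parsed as floats. Rows are preserved in file order.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep=schema.delimiter,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    frame = frame.mask(frame.isin(schema.na_tokens))
    if frame.empty:
        raise ValueError(f"empty dataset: {path}")

    declared = {schema.id_col, *([schema.class_col] if schema.class_col else []),
                *schema.categorical_cols}
    missing_cols = declared - set(frame.columns)
    if missing_cols:
        raise ValueError(f"schema names unknown column(s): {sorted(missing_cols)}")

    ids = frame[schema.id_col]
    if ids.isna().any():
        raise ValueError("missing sample id")
    if ids.duplicated().any():
        raise ValueError(f"duplicate sample ids: {ids[ids.duplicated()].tolist()[:5]}")

    y = None
    drop = [schema.id_col]
    if schema.class_col is not None:
        y = frame[schema.class_col].copy()
        drop.append(schema.class_col)
    X = frame.drop(columns=drop)
    if X.shape[1] == 0:
        raise ValueError("empty dataset: no feature columns")
    X.index = pd.Index(ids.astype(str), name=schema.id_col)
    if y is not None:
        y.index = X.index

    for col in X.columns:
        if col not in schema.categorical_cols:
            X[col] = pd.to_numeric(X[col])
    return TabularDataset(X=X, y=y, categorical=tuple(schema.categorical_cols))


def omit_missing(ds: TabularDataset) -> TabularDataset:
    """Drop every sample with one or more missing cells.

    The class label counts as a required cell: a row lacking its label is
    dropped too. Surviving rows keep their order and values untouched.
    """
    keep = ~ds.X.isna().any(axis=1)
    if ds.y is not None:
        keep &= ~ds.y.isna()
    if not keep.any():
        raise ValueError("no complete samples after omitting missing data")
    y = None if ds.y is None else ds.y[keep]
    return replace(ds, X=ds.X[keep], y=y)


def labelize(ds: TabularDataset) -> tuple[TabularDataset, LabelEncoding]:
    """Map every categorical token to a contiguous integer code.

    The feature count is unchanged (no dummy columns). Token order is
    lexicographic, making codes reproducible. Returns the coded dataset and
    the fitted :class:`LabelEncoding` for reuse on test data.
    """
    if ds.X.isna().any().any():
        raise ValueError("labelize requires a cleaned dataset")
    mapping: dict[str, dict[str, int]] = {}
    X = ds.X.copy()
    for col in ds.categorical:
        tokens = sorted(X[col].astype(str).unique())
        codes = {tok: i for i, tok in enumerate(tokens)}
        mapping[col] = codes
        X[col] = X[col].astype(str).map(codes).astype(np.int64)
    class_order: tuple = ()
    if ds.y is not None:
        class_order = tuple(sorted(ds.y.unique(), key=str))
    enc = LabelEncoding(mapping=mapping, class_order=class_order)
    return replace(ds, X=X), enc


def apply_encoding(ds: TabularDataset, enc: LabelEncoding) -> TabularDataset:
    """Re-apply a fitted encoding to (test) data.

    Tokens never seen at fit time get fresh codes above the fitted maximum
    (assigned in lexicographic order), so they mismatch every training
    category under the L0 metric without colliding with any of them.
    """
    X = ds.X.copy()
    for col in ds.categorical:
        codes = dict(enc.mapping.get(col, {}))
        nxt = max(codes.values(), default=-1) + 1
        seen = X[col].astype(str)
        for tok in sorted(set(seen.unique()) - set(codes)):
            codes[tok] = nxt
            nxt += 1
        X[col] = seen.map(codes).astype(np.int64)
    return replace(ds, X=X)


def _ids(prefix: str, n: int) -> pd.Index:
    width = len(str(n - 1))
    return pd.Index([f"{prefix}{i:0{width}d}" for i in range(n)], name="sample_id")


def make_moons_dataset(n: int = 500, noise_sd: float = 0.0, seed: int = 0) -> TabularDataset:
    """Two interleaving half-circle arcs, ``n/2`` points per class.

    The first class traces the upper unit half-circle ``(cos t, sin t)``,
    the second the shifted lower half-circle ``(1 - cos t, 0.5 - sin t)``,
    with ``t`` evenly spaced on ``[0, pi]``. ``noise_sd`` adds isotropic
    Gaussian jitter. Deterministic under a fixed ``seed``.
    """
    if n < 4 or n % 2:
        raise ValueError("n must be an even count >= 4")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    half = n // 2
    t = np.linspace(0.0, np.pi, half)
    outer = np.column_stack([np.cos(t), np.sin(t)])
    inner = np.column_stack([1.0 - np.cos(t), 0.5 - np.sin(t)])
    pts = np.vstack([outer, inner])
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    X = pd.DataFrame(pts, columns=["f0", "f1"], index=_ids("m", n))
    y = pd.Series(["c0"] * half + ["c1"] * half, index=X.index, name="class")
    return TabularDataset(X=X, y=y)


def make_blobs_dataset(
    n: int = 300,
    centers: Sequence[Sequence[float]] = ((-3.0, 0.0), (3.0, 0.0)),
    sd: float = 1.0,
    seed: int = 0,
) -> TabularDataset:
    """Isotropic Gaussian clusters, one class per center, balanced counts."""
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 2:
        raise ValueError("centers must be a list of 2-vectors")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    c = len(centers)
    if n < c or n % c:
        raise ValueError("n must be a positive multiple of the number of centers")
    per = n // c
    rng = np.random.default_rng(seed)
    pts = np.vstack([ctr + rng.normal(scale=sd, size=(per, 2)) for ctr in centers])
    X = pd.DataFrame(pts, columns=["f0", "f1"], index=_ids("b", n))
    y = pd.Series(
        np.repeat([f"c{i}" for i in range(c)], per), index=X.index, name="class"
    )
    return TabularDataset(X=X, y=y)
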