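import numpy as np
import pandas as pd
import pytest

from gsnac.dataio import LabelEncoding, TabularDataset
from gsnac.graphmodel import PruningPolicy, build_raw_graph, fortify_edges, prune_edges
from gsnac.predict import FittedModel
from gsnac.similarity import distances_to_similarities, pairwise_distances
from gsnac.weighting import FeatureWeightVector, NormalizationParams


@pytest.fixture
def micro_dataset() -> TabularDataset:
    """Four samples, two numeric + one categorical feature, two classes.

    The data is already in normalized/coded form, so fitted transforms are
    the identity and hand-computed distances apply directly.
    """
    X = pd.DataFrame(
        {"f0": [0.0, 0.1, 1.0, 0.9], "f1": [0.0, 0.0, 1.0, 1.0],
         "f2": ["x", "x", "y", "y"]},
        index=list("abcd"),
    )
    y = pd.Series(["A", "A", "B", "B"], index=X.index, name="class")
    return TabularDataset(X=X, y=y, categorical=("f2",))


@pytest.fixture
def micro_weights() -> FeatureWeightVector:
    return FeatureWeightVector(
        ("f0", "f1", "f2"), ("numeric", "numeric", "categorical"),
        np.array([0.25, 0.25, 0.5]),
    )


@pytest.fixture
def micro_coded(micro_dataset) -> TabularDataset:
    """The micro dataset with its categorical column labelized (x=0, y=1)."""
    from gsnac.dataio import labelize

    coded, _ = labelize(micro_dataset)
    return coded


@pytest.fixture
def micro_model_factory(micro_coded, micro_weights):
    """Build a FittedModel on the micro data for a given (k, alpha)."""

    def make(k: int = 2, alpha: float = 0.0) -> FittedModel:
        D = pairwise_distances(micro_coded, micro_weights)
        A = distances_to_similarities(D)
        raw = build_raw_graph(A, micro_coded.require_labels().tolist(), micro_coded.sample_ids)
        gcm = fortify_edges(prune_edges(raw, PruningPolicy(k_max=10, k_effective=k)), alpha)
        return FittedModel(
            weights=micro_weights,
            normalizer=NormalizationParams({"f0": (0.0, 1.0), "f1": (0.0, 1.0)}),
            encoding=LabelEncoding({"f2": {"x": 0, "y": 1}}, ("A", "B")),
            max_train_distance=A.max_train_distance,
            k_effective=k,
            gcm=gcm,
            node_features=micro_coded.X,
        )

    return make


def random_micro_dataset(rng: np.random.Generator, with_categorical: bool = True):
    """A small random mixed-feature training set with >=2 samples per class."""
    n = int(rng.integers(4, 9))
    X = pd.DataFrame(
        {"f0": rng.uniform(0, 1, n), "f1": rng.uniform(0, 1, n)},
        index=[f"s{i}" for i in range(n)],
    )
    cats: tuple = ()
    if with_categorical:
        X["f2"] = rng.choice(["p", "q", "r"], n)
        cats = ("f2",)
    labels = np.array(["A", "B"] * (n // 2) + ["A"] * (n % 2))
    rng.shuffle(labels)
    y = pd.Series(labels, index=X.index, name="class")
    return TabularDataset(X=X, y=y, categorical=cats)
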