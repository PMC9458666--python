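"""Shared non-fixture helpers for property tests."""

import numpy as np
import pandas as pd

from gsnac.dataio import TabularDataset
from gsnac.weighting import FeatureWeightVector


def random_mixed_case(seed: int):
    """A small random (already transformed) mixed dataset + weight vector."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    X = pd.DataFrame(
        {
            "f0": rng.uniform(0, 1, n),
            "f1": rng.uniform(0, 1, n),
            "f2": rng.integers(0, 3, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    w = rng.uniform(0.05, 1.0, 3)
    w = w / w.sum()
    wv = FeatureWeightVector(("f0", "f1", "f2"), ("numeric", "numeric", "categorical"), w)
    return TabularDataset(X=X, categorical=("f2",)), wv
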