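"""Two-phase class prediction on the graph classifier model.

A test sample is attached to the GCM by computing its vectorial similarity
``max(0, max_train_distance - dist(test, v))`` to every node *v*, using the
weights, normalization bounds, category encoding and maximum distance all
frozen at training time.

* **Phase 1 (vectorial)** — per class, average the up-to-k strongest
  similarities. If the top two class scores are separated by more than the
  margin threshold (relative margin ``(s1 - s2)/s1`` by default), assign the
  top class.
* **Phase 2 (topological)** — otherwise compare neighbourhood structure:
  for each node *v*, the cosine between the test's similarity profile and
  *v*'s fortified edge-weight profile over the remaining GCM nodes. The
  per-class mean of the up-to-k highest cosines decides, without a further
  margin check; residual exact ties go to the class with the larger GCM
  support, then to the lexicographically smaller token.

Every prediction returns a :class:`PredictionTrace` naming the contributing
nodes and scores — the explainability artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import LabelEncoding, TabularDataset, apply_encoding
from .similarity import cross_distances
from .weighting import FeatureWeightVector, NormalizationParams, apply_normalizer

__all__ = [
    "FittedModel",
    "TestAttachment",
    "PredictionTrace",
    "attach_test",
    "classwise_vectorial_scores",
    "margin_gate",
    "topological_similarity",
    "predict_one",
    "predict_batch",
    "traces_to_frame",
    "trace_to_dict",
]

VECTORIAL = "vectorial"
TOPOLOGICAL = "topological"


@dataclass(frozen=True)
class FittedModel:
    """Everything frozen at training time that prediction needs."""

    weights: FeatureWeightVector
    normalizer: NormalizationParams
    encoding: LabelEncoding
    max_train_distance: float
    k_effective: int
    gcm: nx.Graph
    node_features: pd.DataFrame  # transformed training rows, indexed by node id

    @property
    def communities(self) -> pd.Series:
        return pd.Series(
            {n: self.gcm.nodes[n]["community"] for n in self.gcm.nodes},
            name="community",
        )

    @property
    def class_support(self) -> dict:
        return self.communities.value_counts().to_dict()

    def transform(self, ds: TabularDataset) -> TabularDataset:
        """Apply the fitted encoding and normalization to raw data."""
        return apply_normalizer(apply_encoding(ds, self.encoding), self.normalizer)


@dataclass(frozen=True)
class TestAttachment:
    """Vectorial similarity of one test sample to every GCM node."""

    test_id: str
    sims: pd.Series  # indexed by GCM node id, all >= 0


@dataclass(frozen=True)
class PredictionTrace:
    """Per-test explanation: who voted, how strongly, and which phase decided.

    ``class_scores`` and ``contributors`` belong to the deciding phase;
    ``vectorial_scores`` (phase 1) are always recorded, as is the phase-1
    margin that triggered — or skipped — the topological fallback.
    """

    test_id: str
    phase: str
    predicted_class: object
    margin: float
    class_scores: dict = field(default_factory=dict)
    contributors: dict = field(default_factory=dict)
    vectorial_scores: dict = field(default_factory=dict)


def _sims_from_distances(d_row: np.ndarray, max_train_distance: float) -> np.ndarray:
    return np.maximum(0.0, max_train_distance - d_row)


def attach_test(test: pd.Series, model: FittedModel, test_id: str = "test") -> TestAttachment:
    """Connect one (already transformed) test sample to every GCM node."""
    expected = set(model.node_features.columns)
    if set(test.index) < expected:
        raise ValueError(f"test sample lacks features {sorted(expected - set(test.index))}")
    probe = TabularDataset(
        X=pd.DataFrame([test[model.node_features.columns]], index=[test_id]),
        categorical=tuple(c for c in model.weights.categorical[0]),
    )
    d = cross_distances(probe, model.node_features, model.weights)[0]
    sims = pd.Series(
        _sims_from_distances(d, model.max_train_distance),
        index=model.node_features.index,
        name=test_id,
    )
    return TestAttachment(test_id=test_id, sims=sims)


def _classwise_topk(
    values: pd.Series, communities: pd.Series, k: int
) -> tuple[dict, dict]:
    """Per-class mean of the up-to-k largest values; also the contributors.

    Within a class, values sort descending with lexicographic node-id
    tie-break. A class whose values are all zero scores 0.
    """
    scores: dict = {}
    contribs: dict = {}
    for cls in sorted(communities.unique(), key=str):
        members = communities.index[communities == cls]
        vals = values[members]
        order = sorted(vals.items(), key=lambda kv: (-kv[1], str(kv[0])))[:k]
        contribs[cls] = [(node, float(v)) for node, v in order]
        scores[cls] = float(np.mean([v for _, v in order])) if order else 0.0
    return scores, contribs


def classwise_vectorial_scores(att: TestAttachment, gcm: nx.Graph, k: int) -> dict:
    """Mean of each class's up-to-k strongest vectorial similarities."""
    communities = pd.Series({n: gcm.nodes[n]["community"] for n in gcm.nodes})
    scores, _ = _classwise_topk(att.sims, communities, k)
    return scores


def margin_gate(
    scores: Mapping, threshold: float = 0.01, mode: str = "relative"
) -> tuple[bool, object, float]:
    """Decide whether the top class wins by a sufficient margin.

    Relative margin is ``(s1 - s2) / s1`` for the top two scores (1 when a
    single class is present, 0 when the best score is 0); absolute mode uses
    ``s1 - s2`` directly. Decided iff margin > threshold.
    """
    if not scores:
        raise ValueError("no class scores")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    top_class, s1 = ranked[0]
    if len(ranked) == 1:
        return True, top_class, 1.0
    s2 = ranked[1][1]
    if mode == "relative":
        margin = 0.0 if s1 <= 0 else (s1 - s2) / s1
    elif mode == "absolute":
        margin = s1 - s2
    else:
        raise ValueError(f"unknown margin mode {mode!r}")
    return margin > threshold, top_class, float(margin)


def topological_similarity(att: TestAttachment, gcm: nx.Graph, v) -> float:
    """Cosine between the test's similarity profile and v's neighbourhood.

    Both vectors live on the common index space of all GCM nodes except *v*
    itself: the test side holds vectorial similarities, the v side holds
    fortified edge weights (0 where no edge). An isolated *v* scores 0.
    """
    if v not in gcm:
        raise KeyError(f"unknown node {v!r}")
    others = [n for n in att.sims.index if n != v]
    t_vec = att.sims[others].to_numpy(dtype=float)
    v_vec = np.array(
        [gcm.edges[v, n]["fortified_weight"] if gcm.has_edge(v, n) else 0.0 for n in others]
    )
    nt = np.linalg.norm(t_vec)
    nv = np.linalg.norm(v_vec)
    if nt == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(t_vec, v_vec) / (nt * nv))


def _decide_from_att(
    att: TestAttachment,
    model: FittedModel,
    threshold: float,
    margin_mode: str,
) -> PredictionTrace:
    communities = model.communities
    k = model.k_effective
    vec_scores, vec_contribs = _classwise_topk(att.sims, communities, k)
    decided, top_class, margin = margin_gate(vec_scores, threshold, margin_mode)
    if decided:
        return PredictionTrace(
            test_id=att.test_id,
            phase=VECTORIAL,
            predicted_class=top_class,
            margin=margin,
            class_scores=vec_scores,
            contributors=vec_contribs,
            vectorial_scores=vec_scores,
        )
    topo = pd.Series(
        {v: topological_similarity(att, model.gcm, v) for v in att.sims.index}
    )
    topo_scores, topo_contribs = _classwise_topk(topo, communities, k)
    support = model.class_support
    winner = sorted(
        topo_scores.items(), key=lambda kv: (-kv[1], -support.get(kv[0], 0), str(kv[0]))
    )[0][0]
    return PredictionTrace(
        test_id=att.test_id,
        phase=TOPOLOGICAL,
        predicted_class=winner,
        margin=margin,
        class_scores=topo_scores,
        contributors=topo_contribs,
        vectorial_scores=vec_scores,
    )


def predict_one(
    test: pd.Series,
    model: FittedModel,
    threshold: float = 0.01,
    margin_mode: str = "relative",
    test_id: str = "test",
    transformed: bool = False,
) -> PredictionTrace:
    """Predict the class of a single raw test sample, with full trace."""
    if model.gcm.number_of_nodes() == 0:
        raise ValueError("empty GCM")
    if not transformed:
        ds = TabularDataset(
            X=pd.DataFrame([test], index=[test_id]),
            categorical=tuple(model.encoding.mapping),
        )
        test = model.transform(ds).X.iloc[0]
    att = attach_test(test, model, test_id=test_id)
    return _decide_from_att(att, model, threshold, margin_mode)


def predict_batch(
    tests: TabularDataset,
    model: FittedModel,
    threshold: float = 0.01,
    margin_mode: str = "relative",
) -> list[PredictionTrace]:
    """Predict each test row independently (no test-test edges), in order."""
    if model.gcm.number_of_nodes() == 0:
        raise ValueError("empty GCM")
    transformed = model.transform(tests)
    d = cross_distances(transformed, model.node_features, model.weights)
    traces = []
    for i, tid in enumerate(transformed.sample_ids):
        sims = pd.Series(
            _sims_from_distances(d[i], model.max_train_distance),
            index=model.node_features.index,
            name=tid,
        )
        att = TestAttachment(test_id=tid, sims=sims)
        traces.append(_decide_from_att(att, model, threshold, margin_mode))
    return traces


def traces_to_frame(traces: Sequence[PredictionTrace]) -> pd.DataFrame:
    """One row per (test, class): contributors, aggregate, margin, phase."""
    rows = []
    for tr in traces:
        for cls, score in sorted(tr.class_scores.items(), key=lambda kv: str(kv[0])):
            rows.append(
                {
                    "test_id": tr.test_id,
                    "class": cls,
                    "aggregate": score,
                    "contributors": ";".join(
                        f"{node}:{val:.6g}" for node, val in tr.contributors.get(cls, [])
                    ),
                    "margin": tr.margin,
                    "phase": tr.phase,
                    "predicted_class": tr.predicted_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["test_id", "class", "aggregate", "contributors",
                 "margin", "phase", "predicted_class"],
    )


def trace_to_dict(trace: PredictionTrace) -> dict:
    """JSON-ready document for one prediction."""
    return {
        "test_id": trace.test_id,
        "phase": trace.phase,
        "predicted_class": str(trace.predicted_class),
        "margin": trace.margin,
        "classes": {
            str(cls): {
                "aggregate": trace.class_scores[cls],
                "contributors": [[str(n), v] for n, v in trace.contributors.get(cls, [])],
            }
            for cls in trace.class_scores
        },
        "vectorial_scores": {str(c): s for c, s in trace.vectorial_scores.items()},
    }
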