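"""Two-phase prediction: attachment, class scores, margin gate, cosine
fallback and trace consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from gsnac.dataio import LabelEncoding, TabularDataset
from gsnac.predict import (
    FittedModel,
    attach_test,
    classwise_vectorial_scores,
    margin_gate,
    predict_batch,
    predict_one,
    topological_similarity,
    traces_to_frame,
)
from gsnac.weighting import FeatureWeightVector, NormalizationParams

# transformed space (categorical already coded) — for attach_test and friends
MICRO_TEST = pd.Series({"f0": 0.05, "f1": 0.0, "f2": 0})
# raw token space — for the transforming predict_one / predict_batch paths
MICRO_TEST_RAW = pd.Series({"f0": 0.05, "f1": 0.0, "f2": "x"})


class TestAttachTest:
    def test_micro_sims_to_five_decimals(self, micro_model_factory):
        att = attach_test(MICRO_TEST, micro_model_factory(k=2))
        # frozen from the loop oracle (hybrid distance + subtract-from-max)
        assert att.sims["a"] == pytest.approx(0.84103, abs=5e-6)
        assert att.sims["b"] == pytest.approx(0.84103, abs=5e-6)
        assert att.sims["c"] == pytest.approx(0.01419, abs=5e-6)
        assert att.sims["d"] == pytest.approx(0.04103, abs=5e-6)

    def test_micro_sims_match_oracle_exactly(self, micro_model_factory, micro_coded, micro_weights):
        model = micro_model_factory(k=2)
        att = attach_test(MICRO_TEST, model)
        want = oracle.test_sims(
            [0.05, 0.0], [0],
            micro_coded.X[["f0", "f1"]].to_numpy().tolist(),
            micro_coded.X[["f2"]].to_numpy().tolist(),
            list(micro_weights.weights[:2]), [micro_weights.weights[2]],
            list(micro_coded.sample_ids), model.max_train_distance,
        )
        for node, v in want.items():
            assert att.sims[node] == pytest.approx(v, abs=1e-12)

    def test_duplicate_of_training_node_is_maximal(self, micro_model_factory, micro_coded):
        model = micro_model_factory(k=2)
        att = attach_test(micro_coded.X.loc["a"], model)
        assert att.sims["a"] == pytest.approx(model.max_train_distance)

    def test_beyond_max_distance_clips_to_zero(self, micro_model_factory):
        att = attach_test(pd.Series({"f0": 5.0, "f1": 5.0, "f2": 9}),
                          micro_model_factory(k=2))
        assert att.sims["a"] == 0.0

    def test_missing_feature_errors(self, micro_model_factory):
        with pytest.raises(ValueError, match="lacks features"):
            attach_test(pd.Series({"f0": 0.1}), micro_model_factory(k=2))


class TestClasswiseScores:
    def test_micro_k2_means(self, micro_model_factory):
        model = micro_model_factory(k=2)
        att = attach_test(MICRO_TEST, model)
        scores = classwise_vectorial_scores(att, model.gcm, 2)
        assert scores["A"] == pytest.approx(0.84103, abs=5e-6)
        assert scores["B"] == pytest.approx(0.02761, abs=5e-6)

    def test_single_class_forced(self, micro_model_factory):
        model = micro_model_factory(k=2)
        gcm = model.gcm.copy()
        for n in gcm.nodes:
            gcm.nodes[n]["community"] = "A"
        att = attach_test(MICRO_TEST, model)
        scores = classwise_vectorial_scores(att, gcm, 2)
        assert list(scores) == ["A"]
        decided, top, margin = margin_gate(scores)
        assert decided and top == "A" and margin == 1.0

    def test_all_zero_sims_score_zero(self, micro_model_factory):
        model = micro_model_factory(k=2)
        att = attach_test(pd.Series({"f0": 50.0, "f1": 50.0, "f2": 7}), model)
        scores = classwise_vectorial_scores(att, model.gcm, 2)
        assert scores == {"A": 0.0, "B": 0.0}
        decided, _, margin = margin_gate(scores)
        assert not decided and margin == 0.0


class TestMarginGate:
    def test_micro_scores_decided(self):
        decided, top, margin = margin_gate({"A": 0.84103, "B": 0.02763})
        assert decided and top == "A"
        assert margin == pytest.approx(0.9671, abs=5e-5)

    def test_close_scores_undecided(self):
        decided, _, margin = margin_gate({"A": 0.500, "B": 0.498}, threshold=0.01)
        assert not decided
        assert margin == pytest.approx(0.004)

    def test_equal_top_scores_margin_zero(self):
        decided, _, margin = margin_gate({"A": 0.4, "B": 0.4})
        assert not decided and margin == 0.0

    def test_absolute_mode(self):
        decided, _, margin = margin_gate({"A": 0.5, "B": 0.3}, threshold=0.1, mode="absolute")
        assert decided and margin == pytest.approx(0.2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6),
           s1=st.floats(min_value=1e-3, max_value=1.0),
           gap=st.floats(min_value=0.0, max_value=0.5))
    def test_scale_invariance_of_relative_margin(self, scale, s1, gap):
        """Scaling all similarities leaves the margin and decision unchanged."""
        s2 = s1 * (1 - gap)
        d1, t1, m1 = margin_gate({"A": s1, "B": s2})
        d2, t2, m2 = margin_gate({"A": s1 * scale, "B": s2 * scale})
        assert (d1, t1) == (d2, t2)
        assert m1 == pytest.approx(m2, abs=1e-9)


class TestTopologicalSimilarity:
    def test_colinear_neighbourhood_gives_one(self, micro_model_factory):
        model = micro_model_factory(k=2, alpha=0.0)
        gcm = model.gcm
        att = attach_test(MICRO_TEST, model)
        # craft v whose edge weights are proportional to the test's sims
        v = "a"
        for n in list(gcm.nodes):
            if n != v:
                if gcm.has_edge(v, n):
                    gcm.edges[v, n]["fortified_weight"] = 2.0 * att.sims[n]
                else:
                    gcm.add_edge(v, n, vectorial_weight=att.sims[n],
                                 fortified_weight=2.0 * att.sims[n])
        assert topological_similarity(att, gcm, v) == pytest.approx(1.0)

    def test_isolated_node_scores_zero(self, micro_model_factory):
        model = micro_model_factory(k=1, alpha=0.0)
        gcm = model.gcm.copy()
        gcm.remove_edges_from(list(gcm.edges("b")))
        att = attach_test(MICRO_TEST, model)
        assert topological_similarity(att, gcm, "b") == 0.0

    def test_micro_k1_matches_dot_product_oracle(self, micro_model_factory):
        model = micro_model_factory(k=1, alpha=0.0)
        att = attach_test(MICRO_TEST, model)
        ids = list(att.sims.index)
        edge_w = {
            frozenset((u, v)): d["fortified_weight"]
            for u, v, d in model.gcm.edges(data=True)
        }
        for v in ids:
            want = oracle.cosine(att.sims.to_dict(), edge_w, v, ids)
            assert topological_similarity(att, model.gcm, v) == pytest.approx(want, abs=1e-12)


def two_node_model() -> FittedModel:
    import networkx as nx

    g = nx.Graph(stage="GCM", alpha=0.0)
    g.add_node("u", community="A", weighted_degree=0.4)
    g.add_node("v", community="B", weighted_degree=0.4)
    g.add_edge("u", "v", vectorial_weight=0.4, fortified_weight=0.4)
    feats = pd.DataFrame({"f0": [0.0, 1.0]}, index=["u", "v"])
    return FittedModel(
        weights=FeatureWeightVector(("f0",), ("numeric",), np.array([1.0])),
        normalizer=NormalizationParams({"f0": (0.0, 1.0)}),
        encoding=LabelEncoding({}, ("A", "B")),
        max_train_distance=1.0,
        k_effective=1,
        gcm=g,
        node_features=feats,
    )


class TestPredictOne:
    def test_micro_phase1_predicts_A(self, micro_model_factory):
        trace = predict_one(MICRO_TEST_RAW, micro_model_factory(k=2), test_id="t")
        assert trace.predicted_class == "A"
        assert trace.phase == "vectorial"
        assert trace.margin == pytest.approx(0.96717, abs=5e-6)

    def test_equidistant_two_node_tie_breaks_lexicographically(self):
        trace = predict_one(pd.Series({"f0": 0.5}), two_node_model())
        assert trace.phase == "topological"
        assert trace.predicted_class == "A"

    def test_duplicate_training_sample_in_blobs_gets_its_class(self):
        from gsnac.dataio import make_blobs_dataset
        from gsnac.estimator import GSNAcClassifier

        ds = make_blobs_dataset(40, sd=0.3, seed=5)
        clf = GSNAcClassifier().fit(ds)
        row = ds.X.iloc[[3]]
        assert clf.predict(row)[0] == ds.y.iloc[3]

    def test_trace_aggregate_equals_mean_of_contributors(self, micro_model_factory):
        for k in (1, 2):
            trace = predict_one(MICRO_TEST_RAW, micro_model_factory(k=k))
            for cls, score in trace.class_scores.items():
                vals = [v for _, v in trace.contributors[cls]]
                assert len(vals) <= k
                assert score == pytest.approx(np.mean(vals), abs=1e-12)


class TestPredictBatch:
    @pytest.fixture
    def micro_tests(self):
        X = pd.DataFrame(
            {"f0": [0.05, 0.95, 0.5], "f1": [0.0, 1.0, 0.4], "f2": ["x", "y", "x"]},
            index=["t1", "t2", "t3"],
        )
        return TabularDataset(X=X, categorical=("f2",))

    def test_batch_of_one_equals_predict_one(self, micro_model_factory, micro_tests):
        model = micro_model_factory(k=2)
        single = predict_one(micro_tests.X.iloc[0], model, test_id="t1")
        batch = predict_batch(micro_tests.subset(["t1"]), model)
        assert batch[0].predicted_class == single.predicted_class
        assert batch[0].class_scores == single.class_scores

    def test_permuting_tests_permutes_traces(self, micro_model_factory, micro_tests):
        model = micro_model_factory(k=2)
        fwd = {t.test_id: t.predicted_class for t in predict_batch(micro_tests, model)}
        rev = {
            t.test_id: t.predicted_class
            for t in predict_batch(micro_tests.subset(["t3", "t1", "t2"]), model)
        }
        assert fwd == rev

    def test_removing_a_row_leaves_others_identical(self, micro_model_factory, micro_tests):
        model = micro_model_factory(k=2)
        full = {t.test_id: t for t in predict_batch(micro_tests, model)}
        part = {t.test_id: t for t in predict_batch(micro_tests.subset(["t1", "t3"]), model)}
        for tid in ("t1", "t3"):
            assert part[tid].class_scores == full[tid].class_scores
            assert part[tid].predicted_class == full[tid].predicted_class

    def test_traces_frame_layout(self, micro_model_factory, micro_tests):
        model = micro_model_factory(k=2)
        frame = traces_to_frame(predict_batch(micro_tests, model))
        assert len(frame) == 3 * 2  # one row per (test, class)
        assert set(frame["phase"]) <= {"vectorial", "topological"}


class TestNoPruningReduction:
    """With alpha=0 and k >= n-1 the pipeline must reduce to the argmax of
    class-mean clipped vectorial similarity over all training nodes."""

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_argmax(self, seed):
        from conftest import random_micro_dataset
        from pipeline_cases import fit_function_pipeline

        rng = np.random.default_rng(seed)
        train = random_micro_dataset(rng)
        n = train.n_samples
        model = fit_function_pipeline(train, k_max=n, k_effective=n - 1, alpha=0.0)

        test = random_micro_dataset(rng)
        traces = predict_batch(test, model, threshold=0.0)
        want = oracle_predictions(train, test)
        got = {t.test_id: t.predicted_class for t in traces}
        assert got == want


def oracle_predictions(train, test):
    """Loop-only replica of transforms + similarity + class-mean argmax."""
    num = [c for c in train.feature_names if c not in train.categorical]
    cat = list(train.categorical)
    tr_num = [
        [oracle.minmax(train.X[c].tolist(), x) for c, x in zip(num, row)]
        for row in train.X[num].to_numpy()
    ]
    tr_cat = train.X[cat].to_numpy().tolist() if cat else [[] for _ in range(train.n_samples)]
    labels = train.require_labels().tolist()
    cols = list(zip(*tr_num)) if num else []
    cat_codes = [
        [sorted(set(train.X[c])).index(v) for c, v in zip(cat, row)]
        for row in train.X[cat].to_numpy()
    ] if cat else [[] for _ in range(train.n_samples)]
    code_cols = list(zip(*cat_codes)) if cat else []
    scores = oracle.anova_f(list(cols) + list(code_cols), labels)
    w = oracle.normalize_weights(scores)
    w_num, w_cat = w[: len(num)], w[len(num):]
    D = oracle.distance_matrix(tr_num, tr_cat, w_num, w_cat)
    _, dmax = oracle.similarities(D)
    ids = list(train.sample_ids)
    classes = dict(zip(ids, labels))
    out = {}
    for tid, row in test.X.iterrows():
        t_num = [oracle.minmax(train.X[c].tolist(), row[c]) for c in num]
        t_cat = [row[c] for c in cat]
        sims = oracle.test_sims(t_num, t_cat, tr_num, tr_cat, w_num, w_cat, ids, dmax)
        out[str(tid)] = oracle.argmax_classmean(sims, classes)
    return out
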