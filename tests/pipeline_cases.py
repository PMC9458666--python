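"""Helper to run the function-level pipeline with explicit knobs, exposing
every intermediate for oracle comparison."""

from gsnac.dataio import labelize
from gsnac.graphmodel import (
    PruningPolicy,
    build_raw_graph,
    choose_k,
    fortify_edges,
    prune_edges,
)
from gsnac.predict import FittedModel
from gsnac.similarity import distances_to_similarities, pairwise_distances
from gsnac.weighting import anova_f_scores, apply_normalizer, feature_weights, fit_normalizer


def fit_function_pipeline(train, k_max=10, k_effective=None, alpha=0.5,
                          return_intermediates=False):
    coded, encoding = labelize(train)
    normalizer = fit_normalizer(coded)
    transformed = apply_normalizer(coded, normalizer)
    scores = anova_f_scores(transformed)
    weights = feature_weights(scores, kinds=transformed.feature_kinds)
    D = pairwise_distances(transformed, weights)
    A = distances_to_similarities(D)
    labels = transformed.require_labels()
    raw = build_raw_graph(A, labels.tolist(), transformed.sample_ids)
    if k_effective is None:
        k_effective = choose_k(labels.value_counts().to_dict(), k_max)
    pruned = prune_edges(raw, PruningPolicy(k_max=max(k_max, k_effective),
                                            k_effective=k_effective))
    gcm = fortify_edges(pruned, alpha)
    model = FittedModel(
        weights=weights,
        normalizer=normalizer,
        encoding=encoding,
        max_train_distance=A.max_train_distance,
        k_effective=k_effective,
        gcm=gcm,
        node_features=transformed.X,
    )
    if return_intermediates:
        return model, {
            "transformed": transformed,
            "scores": scores,
            "D": D,
            "A": A,
            "raw": raw,
            "pruned": pruned,
        }
    return model
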