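"""Stratified cross-validation and baseline benchmarking.

Fold policy: 2 folds when the least-represented class is small (the class
balance priority — every fold must still contain each class), otherwise 5
folds (the high-representation priority — more training nodes per graph).
Folds are stratified by per-class seeded shuffle followed by round-robin
assignment, so each fold carries approximately the global class
proportions. Scoring is the support-weighted F1.

The benchmark harness runs a roster of established classifiers on the
*identical* fold plan for paired comparison; baselines are invoked from
scikit-learn (and xgboost when importable), never re-implemented, each
behind a standardization step as is customary for scale-sensitive models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import f1_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler

from .dataio import TabularDataset, labelize
from .estimator import GSNAcClassifier

__all__ = [
    "CVPlan",
    "CVResult",
    "BenchmarkReport",
    "choose_folds",
    "stratified_folds",
    "weighted_f1",
    "run_cv",
    "run_benchmark",
    "default_roster",
]


@dataclass(frozen=True)
class CVPlan:
    """Sample -> fold assignment produced by stratified splitting."""

    n_folds: int
    assignments: dict
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [sid for sid, f in self.assignments.items() if f == fold]

    def complement_ids(self, fold: int) -> list:
        return [sid for sid, f in self.assignments.items() if f != fold]


@dataclass(frozen=True)
class CVResult:
    """Per-fold and mean weighted F1 plus every prediction trace."""

    fold_scores: tuple
    mean_score: float
    traces: tuple  # tuple of per-fold tuples of PredictionTrace
    plan: CVPlan
    params: dict


@dataclass(frozen=True)
class BenchmarkReport:
    """Paired comparison of classifiers on a shared fold plan."""

    fold_f1: pd.DataFrame        # classifiers x folds
    mean_f1: pd.Series
    ranks: pd.Series             # 1 = best; ties share the better rank
    correctness: pd.DataFrame    # samples x classifiers, boolean
    skipped: tuple = ()
    seed: int = 0
    n_folds: int = 5


def choose_folds(class_counts: Mapping, low_represented_threshold: int = 10) -> int:
    """2 folds when any class is low-represented, else 5."""
    if not class_counts:
        raise ValueError("empty class counts")
    least = min(class_counts.values())
    if least < 2:
        raise ValueError("class not splittable: fewer than 2 samples")
    return 2 if least < low_represented_threshold else 5


def stratified_folds(ds: TabularDataset, n_folds: int, seed: int = 0) -> CVPlan:
    """Per-class seeded shuffle then round-robin fold assignment."""
    y = ds.require_labels()
    counts = y.value_counts()
    too_small = counts[counts < n_folds]
    if not too_small.empty:
        raise ValueError(
            f"classes with fewer samples than folds: {sorted(map(str, too_small.index))}"
        )
    rng = np.random.default_rng(seed)
    assignments: dict = {}
    for cls in sorted(y.unique(), key=str):
        members = [sid for sid, c in zip(ds.sample_ids, y) if c == cls]
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            assignments[members[idx]] = pos % n_folds
    # preserve dataset order in the mapping
    assignments = {sid: assignments[sid] for sid in ds.sample_ids}
    return CVPlan(n_folds=n_folds, assignments=assignments, seed=seed)


def weighted_f1(y_true, y_pred) -> float:
    """Class-wise F1 averaged with true-class support weights."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal lengths")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


def run_cv(
    ds: TabularDataset,
    seed: int = 0,
    n_folds: int | None = None,
    **gsnac_params,
) -> CVResult:
    """Cross-validate the full pipeline; everything refit per fold.

    Normalization bounds, ANOVA weights, the training max distance, the
    effective k and the GCM itself are recomputed from the training folds
    only — the held-out fold never leaks into the model.
    """
    y = ds.require_labels()
    if n_folds is None:
        n_folds = choose_folds(y.value_counts().to_dict())
    plan = stratified_folds(ds, n_folds, seed)
    fold_scores = []
    all_traces = []
    for fold in range(n_folds):
        train = ds.subset(plan.complement_ids(fold))
        test = ds.subset(plan.fold_ids(fold))
        clf = GSNAcClassifier(categorical_features=ds.categorical, **gsnac_params)
        clf.fit(train)
        traces = clf.predict_traces(test)
        preds = [t.predicted_class for t in traces]
        fold_scores.append(weighted_f1(test.require_labels().to_numpy(), preds))
        all_traces.append(tuple(traces))
    return CVResult(
        fold_scores=tuple(fold_scores),
        mean_score=float(np.mean(fold_scores)),
        traces=tuple(all_traces),
        plan=plan,
        params=dict(gsnac_params, seed=seed, n_folds=n_folds),
    )


class _EncodedTarget(ClassifierMixin, BaseEstimator):
    """Adapter encoding class tokens as integers (xgboost requires it)."""

    def __init__(self, base=None):
        self.base = base

    def fit(self, X, y):
        self.encoder_ = LabelEncoder().fit(y)
        self.model_ = clone(self.base).fit(X, self.encoder_.transform(y))
        self.classes_ = self.encoder_.classes_
        return self

    def predict(self, X):
        return self.encoder_.inverse_transform(np.asarray(self.model_.predict(X), dtype=int))


def default_roster(random_state: int = 0) -> dict[str, Callable[[], object]]:
    """Factories for the comparison classifiers, default parameters.

    The ANN gets 2000 iterations (it rarely converges in 200); everything
    else runs stock. Scale-sensitive baselines sit behind a standardizer.
    """

    def _std(est):
        return make_pipeline(StandardScaler(), est)

    def _xgboost():
        from xgboost import XGBClassifier

        return _std(_EncodedTarget(XGBClassifier(random_state=random_state)))

    from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
    from sklearn.gaussian_process import GaussianProcessClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "GSNAc": GSNAcClassifier,
        "kNN": lambda: _std(KNeighborsClassifier(n_neighbors=5)),
        "Decision Tree": lambda: _std(DecisionTreeClassifier(random_state=random_state)),
        "Random Forest": lambda: _std(RandomForestClassifier(random_state=random_state)),
        "NB Gaussian": lambda: _std(GaussianNB()),
        "AdaBoost": lambda: _std(AdaBoostClassifier(random_state=random_state)),
        "ANN-MLP": lambda: _std(MLPClassifier(max_iter=2000, random_state=random_state)),
        "SVM Linear": lambda: _std(SVC(kernel="linear", random_state=random_state)),
        "SVM RBF": lambda: _std(SVC(random_state=random_state)),
        "Gaussian Process": lambda: _std(GaussianProcessClassifier(random_state=random_state)),
        "XGBoost": _xgboost,
    }


def run_benchmark(
    ds: TabularDataset,
    roster: Mapping[str, Callable[[], object]] | None = None,
    seed: int = 0,
    n_folds: int | None = None,
) -> BenchmarkReport:
    """Run every roster classifier on one shared stratified fold plan.

    A roster entry whose factory fails (e.g. a missing optional library) is
    skipped with a warning and listed in ``report.skipped``.
    """
    if roster is None:
        roster = default_roster(seed)
    y = ds.require_labels()
    if n_folds is None:
        n_folds = choose_folds(y.value_counts().to_dict())
    plan = stratified_folds(ds, n_folds, seed)
    coded, _ = labelize(ds)  # numeric representation for the baselines

    fold_rows: dict[str, list[float]] = {}
    correct: dict[str, pd.Series] = {}
    skipped: list[str] = []
    for name, factory in roster.items():
        try:
            factory()
        except Exception as exc:  # missing implementation -> skip, note it
            warnings.warn(f"skipping {name}: {exc}", stacklevel=2)
            skipped.append(name)
            continue
        scores = []
        sample_ok = pd.Series(False, index=list(ds.sample_ids))
        for fold in range(n_folds):
            train_ids = plan.complement_ids(fold)
            test_ids = plan.fold_ids(fold)
            est = factory()
            if isinstance(est, GSNAcClassifier):
                est.fit(ds.subset(train_ids))
                preds = est.predict(ds.subset(test_ids))
            else:
                est.fit(
                    coded.X.loc[train_ids].to_numpy(dtype=float),
                    y.loc[train_ids].to_numpy(),
                )
                preds = est.predict(coded.X.loc[test_ids].to_numpy(dtype=float))
            truth = y.loc[test_ids].to_numpy()
            scores.append(weighted_f1(truth, preds))
            sample_ok.loc[test_ids] = np.asarray(preds) == truth
        fold_rows[name] = scores
        correct[name] = sample_ok

    fold_f1 = pd.DataFrame(fold_rows, index=[f"fold{f}" for f in range(n_folds)]).T
    mean_f1 = fold_f1.mean(axis=1).rename("mean_f1")
    ranks = mean_f1.rank(ascending=False, method="min").astype(int).rename("rank")
    correctness = pd.DataFrame(correct)
    return BenchmarkReport(
        fold_f1=fold_f1,
        mean_f1=mean_f1,
        ranks=ranks,
        correctness=correctness,
        skipped=tuple(skipped),
        seed=seed,
        n_folds=n_folds,
    )
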