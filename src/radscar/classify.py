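"""Cross-validated classification of scar vs. normal feature vectors.

Three classical model families — decision tree, RBF-kernel SVM, and
L2-penalized logistic regression — evaluated with stratified k-fold
cross-validation (default k = 5). "Scar" is the positive class
throughout, so sensitivity is the scar detection rate. Confusion counts
are pooled across folds before metrics are computed (micro-average);
per-fold counts are retained in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ClassTooSmallError, UndefinedMetricError
from .features import FeatureVector

MODEL_NAMES = ("decision_tree", "svm", "logistic_regression")

POSITIVE_LABEL = "scar"


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with scar as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class EvalReport:
    """Pooled cross-validation result for one model family."""

    model: str
    sensitivity: float
    specificity: float
    accuracy: float
    folds: int
    seed: int
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_fold"] = [asdict(c) for c in self.per_fold]
        return d


def stratified_kfold(labels, k: int, seed: int):
    """Disjoint stratified test folds as index arrays.

    Every index appears in exactly one fold; per-fold class counts differ
    by at most 1 from perfect proportionality. Shuffling is seeded, so the
    folds are a deterministic function of (labels, k, seed).
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ClassTooSmallError(
            f"smallest class has {counts.min()} members, need >= k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), labels)]


def confusion_metrics(c: ConfusionCounts):
    """(sensitivity, specificity, accuracy) from confusion counts."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no actual positives: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no actual negatives: specificity undefined")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    return sens, spec, acc


def _make_model(name: str, seed: int, tree_params: dict | None):
    if name == "decision_tree":
        params = dict(
            max_depth=None,
            min_samples_split=2,
            min_samples_leaf=1,
            max_leaf_nodes=None,
            class_weight="balanced",
        )
        if tree_params:
            params.update(tree_params)
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "logistic_regression":
        # sklearn's default penalty is already the L2 (ridge) penalty
        return LogisticRegression(C=1.0, max_iter=2000)
    raise ValueError(f"unknown model {name!r}")


def _features_to_xy(features: list[FeatureVector]):
    X = np.stack([np.asarray(f.bins, dtype=np.float64) for f in features])
    y = np.array([1 if f.label == POSITIVE_LABEL else 0 for f in features])
    return X, y


def run_models(
    features: list[FeatureVector],
    k: int = 5,
    seed: int = 0,
    models=MODEL_NAMES,
    tree_params: dict | None = None,
) -> list[EvalReport]:
    """Stratified k-fold evaluation of each model family.

    For each family: fit on k-1 folds, predict the held-out fold, pool the
    confusion counts over folds, compute sensitivity/specificity/accuracy
    from the pooled counts. All randomness (fold shuffling, tree split
    ties) derives from ``seed``, so reports are reproducible bit for bit.
    """
    X, y = _features_to_xy(features)
    folds = stratified_kfold(y, k, seed)
    all_idx = np.arange(len(y))
    reports = []
    for name in models:
        per_fold = []
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            if len(np.unique(y[train_idx])) < 2:
                raise ClassTooSmallError(
                    f"single-class training fold for model {name!r}"
                )
            clf = _make_model(name, seed, tree_params)
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            truth = y[test_idx]
            per_fold.append(
                ConfusionCounts(
                    tp=int(np.sum((pred == 1) & (truth == 1))),
                    fp=int(np.sum((pred == 1) & (truth == 0))),
                    tn=int(np.sum((pred == 0) & (truth == 0))),
                    fn=int(np.sum((pred == 0) & (truth == 1))),
                )
            )
        pooled = per_fold[0]
        for c in per_fold[1:]:
            pooled = pooled + c
        sens, spec, acc = confusion_metrics(pooled)
        reports.append(
            EvalReport(
                model=name,
                sensitivity=sens,
                specificity=spec,
                accuracy=acc,
                folds=k,
                seed=seed,
                per_fold=per_fold,
            )
        )
    return reports
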