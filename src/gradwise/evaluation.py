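"""Cross-validated evaluation of candidate feature sets.

Five supervised models (SVM, logistic regression, KNN, random forest,
AdaBoost) are scored on each candidate set with six metrics — accuracy (as
a percent), ROC AUC, F1, precision, recall/sensitivity and specificity —
averaged over stratified outer folds, with the aggressive grade (class 1)
as the positive class.  The sweep table collects mean accuracy per
(minimum-weight threshold, model) cell, and :func:`select_best` applies the
"highest accuracy with the fewest features" rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data_io import FeatureTable

log = logging.getLogger(__name__)

#: Canonical model names; also the fixed tie-break order in select_best.
MODEL_ORDER = ("svm", "lr", "knn", "rf", "adaboost")
MODEL_DISPLAY = {"svm": "SVM", "lr": "LR", "knn": "KNN", "rf": "RF", "adaboost": "AdaBoost"}


class ConfigError(ValueError):
    """Unknown model or invalid evaluation configuration."""


def make_models(seed: int) -> dict:
    """Registry of the five classifier constructors with fixed settings.

    Hyperparameters are deliberately plain defaults: KNN with k = 5 and
    Euclidean distance; L2 logistic regression with C = 1; RBF SVM with
    C = 1 and gamma scaled by 1/(p * var); a 100-tree random forest; and
    AdaBoost with 50 depth-1 stumps.  The seed is threaded into every
    stochastic model so two calls with the same seed are identical.
    """
    return {
        "svm": lambda: SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        "lr": lambda: LogisticRegression(C=1.0, max_iter=2000),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5, metric="euclidean"),
        "rf": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(n_estimators=50, random_state=seed),
    }


def make_folds(y, n_folds: int, seed: int):
    """One stratified partition reused by both the selection and evaluation
    phases, so a fold's training split is identical in each."""
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in cv.split(np.zeros(len(y)), y)]


@dataclass(frozen=True)
class EvalMetrics:
    """Six-metric summary, each a mean over outer folds.

    ``acc`` is a percent in [0, 100]; the rest are unit-interval floats.
    Recall and specificity are with respect to the positive class
    (aggressive grade = 1).
    """

    acc: float
    auc: float
    f1: float
    pre: float
    rec: float
    spec: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.acc <= 100.0):
            raise ValueError(f"acc must be a percent in [0,100], got {self.acc}")
        for name in ("auc", "f1", "pre", "rec", "spec"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("acc", "auc", "f1", "pre", "rec", "spec")}

    @classmethod
    def from_dict(cls, d: dict) -> "EvalMetrics":
        return cls(**{k: float(d[k]) for k in ("acc", "auc", "f1", "pre", "rec", "spec")})


@dataclass(frozen=True)
class SweepRow:
    """One row of the sweep: a minimum-weight threshold and its candidate set."""

    k: int
    n_features: int
    acc_by_model: dict
    features: tuple | None = None
    metrics_by_model: dict | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_features": self.n_features,
            "acc_by_model": {m: float(a) for m, a in self.acc_by_model.items()},
            "features": list(self.features) if self.features is not None else None,
            "metrics_by_model": (
                {m: em.to_dict() for m, em in self.metrics_by_model.items()}
                if self.metrics_by_model is not None else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepRow":
        return cls(
            k=int(d["k"]),
            n_features=int(d["n_features"]),
            acc_by_model=dict(d["acc_by_model"]),
            features=tuple(d["features"]) if d.get("features") is not None else None,
            metrics_by_model=(
                {m: EvalMetrics.from_dict(em) for m, em in d["metrics_by_model"].items()}
                if d.get("metrics_by_model") else None
            ),
        )


@dataclass(frozen=True)
class SweepTable:
    """Grid of mean accuracies: rows are thresholds k (descending), columns models."""

    rows: tuple
    models: tuple

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("a sweep needs at least one model")
        if not self.rows:
            raise ValueError("a sweep needs at least one row")
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "models", tuple(self.models))
        for row in self.rows:
            missing = [m for m in self.models if m not in row.acc_by_model]
            if missing:
                raise ValueError(f"row k={row.k} lacks accuracies for {missing}")

    def cells(self):
        """Yield (row, model, accuracy) over the whole grid."""
        for row in self.rows:
            for m in self.models:
                yield row, m, float(row.acc_by_model[m])

    def to_dict(self) -> dict:
        return {"models": list(self.models), "rows": [r.to_dict() for r in self.rows]}

    @classmethod
    def from_dict(cls, d: dict) -> "SweepTable":
        return cls(rows=tuple(SweepRow.from_dict(r) for r in d["rows"]),
                   models=tuple(d["models"]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"k": r.k, "# of Features": r.n_features,
                 **{MODEL_DISPLAY.get(m, m): round(float(r.acc_by_model[m]), 3)
                    for m in self.models}}
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class BestConfig:
    """The winning (threshold, model) cell and its feature set."""

    k: int
    model: str
    n_features: int
    accuracy: float
    features: tuple | None = None
    metrics: EvalMetrics | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "model": self.model,
            "n_features": self.n_features,
            "accuracy": float(self.accuracy),
            "features": list(self.features) if self.features is not None else None,
            "metrics": self.metrics.to_dict() if self.metrics is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BestConfig":
        return cls(
            k=int(d["k"]), model=d["model"], n_features=int(d["n_features"]),
            accuracy=float(d["accuracy"]),
            features=tuple(d["features"]) if d.get("features") is not None else None,
            metrics=EvalMetrics.from_dict(d["metrics"]) if d.get("metrics") else None,
        )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return tp, fn, tn, fp


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Accuracy (%), F1, precision, recall, specificity from one confusion
    matrix.  Undefined ratios (zero denominators) are recorded as 0."""
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); recorded as 0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    acc = 100.0 * (tp + tn) / n
    pre = _ratio(tp, tp + fp, "precision")
    rec = _ratio(tp, tp + fn, "recall")
    spec = _ratio(tn, tn + fp, "specificity")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1")
    return {"acc": acc, "f1": f1, "pre": pre, "rec": rec, "spec": spec}


def _scores_for_auc(model, X: np.ndarray) -> np.ndarray:
    # margin-based models rank by decision values; AUC only needs ordering
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def evaluate_candidate(table: FeatureTable, features, model: str,
                       fold_partition, seed: int,
                       normalize_within_fold=()) -> EvalMetrics:
    """Fit and score one model on one feature subset across the given folds.

    Per fold the model is fit on the training split restricted to
    ``features`` and scored on the test split; threshold metrics come from
    the confusion matrix at the model's default decision rule and AUC from
    continuous scores by the rank-based (trapezoidal ROC) method.  A fold
    whose test split contains a single class gets AUC 0 with a warning.
    Returns the fold means.
    """
    features = tuple(features)
    if not features:
        raise ValueError("candidate feature set is empty")
    registry = make_models(seed)
    if model not in registry:
        raise ConfigError(f"unknown model {model!r}; choose from {sorted(registry)}")
    idx = [table.index_of(f) for f in features]
    X_all, y_all = table.X[:, idx], table.y
    norm_cols = [features.index(f) for f in normalize_within_fold if f in features]

    per_fold = []
    for tr, te in fold_partition:
        X_tr, X_te = X_all[tr].copy(), X_all[te].copy()
        y_tr, y_te = y_all[tr], y_all[te]
        for j in norm_cols:
            mu, sd = float(X_tr[:, j].mean()), float(X_tr[:, j].std())
            if sd > 0:
                X_tr[:, j] = (X_tr[:, j] - mu) / sd
                X_te[:, j] = (X_te[:, j] - mu) / sd
        clf = registry[model]()
        clf.fit(X_tr, y_tr)
        y_pred = clf.predict(X_te)
        fold = metrics_from_confusion(*_confusion(y_te, y_pred))
        if len(np.unique(y_te)) < 2:
            warnings.warn("single-class test fold: AUC undefined, recorded as 0",
                          RuntimeWarning, stacklevel=2)
            fold["auc"] = 0.0
        else:
            fold["auc"] = float(roc_auc_score(y_te, _scores_for_auc(clf, X_te)))
        per_fold.append(fold)

    means = {k: float(np.mean([f[k] for f in per_fold])) for k in per_fold[0]}
    return EvalMetrics(**means)


def run_sweep(table: FeatureTable, candidates, models, fold_partition, seed: int,
              normalize_within_fold=()) -> SweepTable:
    """Evaluate every (candidate set, model) cell into a sweep table.

    Empty candidate sets (thresholds above the maximum observed weight) are
    skipped with a logged notice.  Adjacent thresholds often share an
    identical candidate set; each still gets its own row, with the
    deterministic evaluation memoized on the feature tuple.
    """
    models = tuple(models)
    cache: dict = {}
    rows = []
    for cand in candidates:
        feats = tuple(cand.features)
        if not feats:
            log.info("k=%d: empty candidate set, skipped", cand.k)
            continue
        acc_by_model, metrics_by_model = {}, {}
        for m in models:
            key = (feats, m)
            if key not in cache:
                try:
                    cache[key] = evaluate_candidate(
                        table, feats, m, fold_partition, seed,
                        normalize_within_fold=normalize_within_fold,
                    )
                except Exception as exc:  # re-raise with cell coordinates
                    raise RuntimeError(f"evaluation failed at k={cand.k}, model={m}: {exc}") from exc
            em = cache[key]
            acc_by_model[m] = em.acc
            metrics_by_model[m] = em
        log.info("k=%d (%d features): %s", cand.k, len(feats),
                 {m: round(a, 3) for m, a in acc_by_model.items()})
        rows.append(SweepRow(k=cand.k, n_features=len(feats), features=feats,
                             acc_by_model=acc_by_model, metrics_by_model=metrics_by_model))
    if not rows:
        raise ValueError("no non-empty candidate sets to evaluate")
    return SweepTable(rows=tuple(rows), models=models)


def _rank_key(sweep: SweepTable):
    order = {m: i for i, m in enumerate(MODEL_ORDER)}

    def key(cell):
        row, m, acc = cell
        return (-acc, row.n_features, -row.k, order.get(m, len(order)))

    return key


def select_best(sweep: SweepTable) -> BestConfig:
    """Best cell of the sweep: maximum mean accuracy, ties broken by fewer
    features, then larger threshold k, then fixed model order."""
    row, m, acc = min(sweep.cells(), key=_rank_key(sweep))
    return BestConfig(
        k=row.k, model=m, n_features=row.n_features, accuracy=acc,
        features=row.features,
        metrics=row.metrics_by_model[m] if row.metrics_by_model else None,
    )


def select_runner_up(sweep: SweepTable) -> BestConfig:
    """Best cell after excluding every cell tied with the winning accuracy,
    i.e. the second-best *distinct* accuracy under the same rule."""
    best = select_best(sweep)
    remaining = [c for c in sweep.cells() if c[2] != best.accuracy]
    if not remaining:
        raise ValueError("all cells share one accuracy; no distinct runner-up")
    row, m, acc = min(remaining, key=_rank_key(sweep))
    return BestConfig(
        k=row.k, model=m, n_features=row.n_features, accuracy=acc,
        features=row.features,
        metrics=row.metrics_by_model[m] if row.metrics_by_model else None,
    )
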