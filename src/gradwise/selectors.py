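"""Per-fold feature-selection methods.

Two selectors are run on the training split of every cross-validation fold:

* a greedy minimum-redundancy maximum-relevance (mRMR) filter built on a
  plug-in mutual-information estimator, and
* an embedded L1-penalized logistic regression (LASSO) whose penalty is
  chosen by an inner stratified cross-validation over a geometric grid.

Both return :class:`SelectorResult` objects that the weighting stage
aggregates into per-feature integer weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_io import (
    KIND_CONTINUOUS,
    DegenerateFeatureError,
    FeatureTable,
)

METHOD_MRMR = "mrmr"
METHOD_LASSO = "lasso"


@dataclass(frozen=True)
class SelectorResult:
    """Outcome of one selector on one fold's training split."""

    method: str
    fold_index: int
    selected: tuple  # feature names, in selection order where meaningful
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MrmrConfig:
    """Settings for the mRMR filter.

    ``m`` is the subset size; when None it defaults to ``ceil(log2(p))``.
    ``criterion`` is ``difference`` (relevance minus mean redundancy, MID) or
    ``quotient`` (relevance over mean redundancy, MIQ).  Continuous features
    are quantile-discretized into ``n_bins`` bins before estimating mutual
    information.
    """

    m: int | None = None
    criterion: str = "difference"
    n_bins: int = 4

    def __post_init__(self) -> None:
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")
        if self.criterion not in ("difference", "quotient"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class LassoConfig:
    """Settings for the embedded L1 selector.

    ``alpha_grid``: strictly positive, ascending penalty values; when None a
    50-point geometric grid spanning ``[1e-4 * alpha_max, alpha_max]`` is
    built per call, where ``alpha_max`` is the smallest penalty that zeroes
    every coefficient.  The best alpha maximizes mean accuracy over
    ``inner_folds`` stratified folds; ties go to the larger (sparser) alpha.
    """

    alpha_grid: tuple | None = None
    n_alphas: int = 50
    alpha_min_ratio: float = 1e-4
    inner_folds: int = 10
    coef_threshold: float = 1e-8
    max_iter: int = 2000
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.alpha_grid is not None:
            grid = tuple(float(a) for a in self.alpha_grid)
            if any(a <= 0 for a in grid) or list(grid) != sorted(grid):
                raise ValueError("alpha_grid must be positive and ascending")
            object.__setattr__(self, "alpha_grid", grid)


def mrmr_subset_size(p: int) -> int:
    """Heuristic mRMR subset size: ``ceil(log2(p))``.

    For the 23-feature glioma table this gives 5.
    """
    if p < 2:
        raise ValueError(f"need at least 2 features, got {p}")
    return int(math.ceil(math.log2(p)))


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Computes ``sum_ab p(a,b) log2[p(a,b) / (p(a) p(b))]`` from the empirical
    joint distribution, with the convention ``0 * log 0 = 0``.  Symmetric and
    non-negative; equals the empirical entropy when ``x is y``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (px @ py)[mask]
    return float(np.sum(joint[mask] * np.log2(ratio)))


def discretize_continuous(x, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile) binning with labels ``0..n_bins-1``.

    Values exactly on a bin edge go to the lower bin, so the assignment is
    deterministic and invariant to input order.  A vector with at most
    ``n_bins`` distinct values is passed through as its sorted level codes.
    """
    x = np.asarray(x, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise DegenerateFeatureError("cannot discretize a constant vector")
    if distinct.size <= n_bins:
        return np.searchsorted(distinct, x).astype(int)
    edges = np.unique(np.quantile(x, np.arange(1, n_bins) / n_bins))
    return np.searchsorted(edges, x, side="left").astype(int)


def _discretized_matrix(table: FeatureTable, n_bins: int) -> np.ndarray:
    """Columns of the table as discrete codes for MI estimation."""
    cols = []
    for j, kind in enumerate(table.feature_kinds):
        col = table.X[:, j]
        if kind == KIND_CONTINUOUS:
            cols.append(discretize_continuous(col, n_bins))
        else:
            # binary / categorical codes are already discrete
            cols.append(col.astype(int))
    return np.column_stack(cols)


def mrmr_select(table: FeatureTable, config: MrmrConfig | None = None,
                fold_index: int = 0) -> SelectorResult:
    """Greedy forward mRMR selection of exactly ``m`` features.

    The first feature maximizes relevance MI(f; y); each later step
    maximizes relevance minus (difference criterion) or divided by
    (quotient criterion) the mean MI with the already-selected set.  Ties
    are broken toward the lower feature index.
    """
    config = config or MrmrConfig()
    p = table.p
    m = config.m if config.m is not None else mrmr_subset_size(p)
    if m > p:
        raise ValueError(f"m={m} exceeds number of features p={p}")

    D = _discretized_matrix(table, config.n_bins)
    y = table.y
    relevance = np.array([mutual_information(D[:, j], y) for j in range(p)])

    selected: list[int] = []
    step_scores: list[float] = []
    # pairwise MI with selected features, computed lazily
    redundancy = np.zeros((p, 0))
    remaining = list(range(p))
    while len(selected) < m:
        if not selected:
            scores = relevance[remaining]
        else:
            mean_red = redundancy[remaining].mean(axis=1)
            if config.criterion == "difference":
                scores = relevance[remaining] - mean_red
            else:
                scores = relevance[remaining] / np.maximum(mean_red, 1e-12)
        # ties (within floating tolerance) break toward the lower feature index
        best_pos = int(np.argmax(scores >= np.max(scores) - 1e-9))
        j = remaining.pop(best_pos)
        step_scores.append(float(scores[best_pos]))
        new_col = np.array([[mutual_information(D[:, i], D[:, j])] for i in range(p)])
        redundancy = np.hstack([redundancy, new_col])
        selected.append(j)

    names = tuple(table.feature_names[j] for j in selected)
    return SelectorResult(
        method=METHOD_MRMR,
        fold_index=fold_index,
        selected=names,
        diagnostics={
            "step_scores": step_scores,
            "relevance": {table.feature_names[j]: float(relevance[j]) for j in range(p)},
            "criterion": config.criterion,
            "m": m,
        },
    )


def _default_alpha_grid(X: np.ndarray, y: np.ndarray, config: LassoConfig) -> np.ndarray:
    # smallest penalty that zeroes all coefficients of the L1 logistic fit:
    # max |X^T (y - ybar)| / n at the intercept-only solution
    n = X.shape[0]
    resid = y - y.mean()
    alpha_max = float(np.abs(X.T @ resid).max() / n)
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(config.alpha_min_ratio * alpha_max, alpha_max, config.n_alphas)


def _l1_logistic(alpha: float, n: int, config: LassoConfig, seed: int) -> LogisticRegression:
    # scikit-learn parameterizes by C = 1 / (n * alpha) for the mean-loss form
    return LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * alpha),
        solver="liblinear",
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=seed,
    )


def lasso_select(table: FeatureTable, config: LassoConfig | None = None,
                 seed: int = 0, fold_index: int = 0) -> SelectorResult:
    """Embedded selection via L1-penalized logistic regression.

    The penalty is chosen to maximize mean accuracy over inner stratified
    folds (ties favor the larger, sparser penalty); the model is then refit
    at that penalty on the full input and features with coefficient
    magnitude above ``coef_threshold`` are returned.  An empty selection is
    legal when the penalty shrinks every coefficient to zero.
    """
    config = config or LassoConfig()
    X, y = table.X, table.y
    n = X.shape[0]
    if config.alpha_grid is not None:
        grid = np.asarray(config.alpha_grid, dtype=float)
    else:
        grid = _default_alpha_grid(X, y, config)

    n_inner = min(config.inner_folds, int(np.bincount(y).min()))
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        if n_inner >= 2:
            cv = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
            splits = list(cv.split(X, y))
            mean_acc = np.empty(grid.size)
            for a, alpha in enumerate(grid):
                accs = []
                for tr, te in splits:
                    try:
                        clf = _l1_logistic(alpha, len(tr), config, seed)
                        clf.fit(X[tr], y[tr])
                    except ConvergenceWarning:
                        converged = False
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", ConvergenceWarning)
                            clf = _l1_logistic(alpha, len(tr), config, seed)
                            clf.fit(X[tr], y[tr])
                    accs.append(float((clf.predict(X[te]) == y[te]).mean()))
                mean_acc[a] = np.mean(accs)
            # ties -> larger alpha (sparser); grid is ascending
            best = grid.size - 1 - int(np.argmax(mean_acc[::-1]))
            alpha = float(grid[best])
        else:  # degenerate minority class: fall back to the sparsest grid point
            alpha = float(grid[-1])
            mean_acc = np.full(grid.size, np.nan)

        try:
            final = _l1_logistic(alpha, n, config, seed)
            final.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                final = _l1_logistic(alpha, n, config, seed)
                final.fit(X, y)

    coefs = final.coef_.ravel()
    mask = np.abs(coefs) > config.coef_threshold
    names = tuple(name for name, keep in zip(table.feature_names, mask) if keep)
    if not converged:
        warnings.warn("L1 logistic fit did not fully converge; result recorded anyway",
                      RuntimeWarning, stacklevel=2)
    return SelectorResult(
        method=METHOD_LASSO,
        fold_index=fold_index,
        selected=names,
        diagnostics={
            "alpha": alpha,
            "alpha_grid": [float(a) for a in grid],
            "cv_mean_accuracy": [float(a) for a in np.atleast_1d(mean_acc)],
            "coefficients": {n_: float(c) for n_, c in zip(table.feature_names, coefs)},
            "converged": converged,
        },
    )
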