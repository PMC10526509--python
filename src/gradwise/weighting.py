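"""Rank assignment and per-feature weight accumulation across folds.

Each selection method carries an integer rank — by default 2 for the
embedded LASSO and 1 for the mRMR filter, reflecting their standalone
accuracies — and every time a method selects a feature on a fold's
training split, that feature's weight grows by the method's rank.  With 5
folds and ranks {2, 1} the maximum attainable weight is 15; a feature no
method ever picks stays at 0.  Thresholding the ledger at each minimum
weight k produces the nested candidate sets the evaluation stage sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import FeatureTable
from .evaluation import evaluate_candidate
from .selectors import (
    METHOD_LASSO,
    METHOD_MRMR,
    LassoConfig,
    MrmrConfig,
    SelectorResult,
    lasso_select,
    mrmr_select,
)

log = logging.getLogger(__name__)

FIXED_RANKS = {METHOD_LASSO: 2, METHOD_MRMR: 1}


@dataclass(frozen=True)
class MethodRanks:
    """Integer ranks of the two selection methods (higher = more trusted)."""

    rank_by_method: dict
    provenance: str = "fixed"  # "fixed" or "empirical"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rank_by_method) < 2:
            raise ValueError("need ranks for at least two methods")
        for m, r in self.rank_by_method.items():
            if int(r) < 1:
                raise ValueError(f"rank for {m!r} must be a positive integer")

    @property
    def rank_sum(self) -> int:
        return int(sum(self.rank_by_method.values()))

    def to_dict(self) -> dict:
        return {"rank_by_method": dict(self.rank_by_method), "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "MethodRanks":
        return cls(rank_by_method={m: int(r) for m, r in d["rank_by_method"].items()},
                   provenance=d.get("provenance", "fixed"))


@dataclass(frozen=True)
class WeightLedger:
    """Accumulated integer weight per feature over all folds and methods."""

    weights: dict
    n_folds: int
    rank_sum: int

    def __post_init__(self) -> None:
        cap = self.max_possible
        for f, w in self.weights.items():
            if not (0 <= int(w) <= cap):
                raise ValueError(f"weight {w} for {f!r} outside [0, {cap}]")

    @property
    def max_possible(self) -> int:
        return self.n_folds * self.rank_sum

    @property
    def max_observed(self) -> int:
        return max(self.weights.values()) if self.weights else 0

    def sorted_items(self):
        """(feature, weight) pairs, descending weight then name."""
        return sorted(self.weights.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {"weights": dict(self.weights), "n_folds": self.n_folds,
                "rank_sum": self.rank_sum}

    @classmethod
    def from_dict(cls, d: dict) -> "WeightLedger":
        return cls(weights={f: int(w) for f, w in d["weights"].items()},
                   n_folds=int(d["n_folds"]), rank_sum=int(d["rank_sum"]))


@dataclass(frozen=True)
class CandidateSet:
    """Features whose accumulated weight is at least the threshold ``k``."""

    k: int
    features: tuple

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("threshold k must be >= 1")
        object.__setattr__(self, "features", tuple(self.features))


def accumulate_weights(fold_selections, ranks: MethodRanks, n_folds: int,
                       feature_names=None) -> WeightLedger:
    """Sum method ranks over every (fold, method) selection event.

    ``fold_selections`` must cover each (fold, method) pair exactly once.
    When ``feature_names`` is given, never-selected features appear in the
    ledger with weight 0.
    """
    seen = set()
    for res in fold_selections:
        key = (res.fold_index, res.method)
        if key in seen:
            raise ValueError(f"duplicate selection result for fold={res.fold_index}, "
                             f"method={res.method!r}")
        if not (0 <= res.fold_index < n_folds):
            raise ValueError(f"fold index {res.fold_index} outside 0..{n_folds - 1}")
        if res.method not in ranks.rank_by_method:
            raise ValueError(f"no rank assigned to method {res.method!r}")
        seen.add(key)
    expected = {(f, m) for f in range(n_folds) for m in ranks.rank_by_method}
    if seen != expected:
        missing = sorted(expected - seen)
        raise ValueError(f"missing selection results for {missing}")

    weights: dict = {f: 0 for f in (feature_names or ())}
    for res in fold_selections:
        r = int(ranks.rank_by_method[res.method])
        for f in res.selected:
            weights[f] = weights.get(f, 0) + r
    return WeightLedger(weights=weights, n_folds=n_folds, rank_sum=ranks.rank_sum)


def candidate_sets(ledger: WeightLedger, k_values=None):
    """One candidate set per threshold, descending from the maximum possible
    weight down to 1; k = 1 recovers the union of all ever-selected features.
    Empty sets (k above the maximum observed weight) are retained — the
    evaluation stage skips them with a notice."""
    if not ledger.weights:
        raise ValueError("empty ledger")
    if k_values is None:
        k_values = range(ledger.max_possible, 0, -1)
    out = []
    ordered = ledger.sorted_items()
    for k in k_values:
        feats = tuple(f for f, w in ordered if w >= k)
        out.append(CandidateSet(k=int(k), features=feats))
    return out


def run_fold_selections(table: FeatureTable, fold_partition,
                        mrmr_config: MrmrConfig | None = None,
                        lasso_config: LassoConfig | None = None,
                        seed: int = 0, normalize_within_fold=()):
    """Run both selectors on the training split of every fold."""
    results = []
    for i, (tr, _te) in enumerate(fold_partition):
        sub = table.take_rows(tr)
        if normalize_within_fold:
            from .data_io import zscore_continuous

            sub = zscore_continuous(sub, list(normalize_within_fold))
        res_m = mrmr_select(sub, mrmr_config, fold_index=i)
        res_l = lasso_select(sub, lasso_config, seed=seed + 101 + i, fold_index=i)
        log.info("fold %d: mrmr=%s lasso=%s", i, res_m.selected, res_l.selected)
        results.extend([res_m, res_l])
    return results


def baseline_accuracy_grid(table: FeatureTable, models, fold_partition, seed: int,
                           mrmr_config: MrmrConfig | None = None,
                           lasso_config: LassoConfig | None = None,
                           normalize_within_fold=()) -> dict:
    """Mean CV accuracy per model under three regimes: all features
    (without_fs), per-fold LASSO selection only, per-fold mRMR selection
    only.  This is both the with/without-selection comparison panel and the
    evidence for empirical rank assignment."""
    from .evaluation import make_models, metrics_from_confusion, _confusion  # noqa: F401

    selections = run_fold_selections(table, fold_partition, mrmr_config,
                                     lasso_config, seed, normalize_within_fold)
    by_fold_method = {(r.fold_index, r.method): r.selected for r in selections}

    grid: dict = {"without_fs": {}, METHOD_LASSO: {}, METHOD_MRMR: {}}
    for model in models:
        full = evaluate_candidate(table, table.feature_names, model, fold_partition,
                                  seed, normalize_within_fold=normalize_within_fold)
        grid["without_fs"][model] = full.acc
    for method in (METHOD_LASSO, METHOD_MRMR):
        for model in models:
            accs = []
            for i, (tr, te) in enumerate(fold_partition):
                feats = by_fold_method[(i, method)]
                if not feats:  # an all-shrunk LASSO fold predicts the majority class
                    maj = int(np.bincount(table.y[tr]).argmax())
                    accs.append(100.0 * float((table.y[te] == maj).mean()))
                    continue
                em = evaluate_candidate(table, feats, model, [(tr, te)], seed,
                                        normalize_within_fold=normalize_within_fold)
                accs.append(em.acc)
            grid[method][model] = float(np.mean(accs))
    return grid


def assign_ranks(table: FeatureTable, models, folds, seed: int,
                 mode: str = "fixed",
                 mrmr_config: MrmrConfig | None = None,
                 lasso_config: LassoConfig | None = None,
                 normalize_within_fold=()) -> MethodRanks:
    """Rank the two selection methods.

    ``fixed`` returns {lasso: 2, mrmr: 1} verbatim.  ``empirical`` scores
    each method standalone (per-fold selection plus per-fold model fits,
    best mean accuracy over the model list) and gives rank 2 to the winner;
    an exact tie keeps the canonical order (lasso 2, mrmr 1).  ``folds``
    may be a fold count or a precomputed partition.
    """
    if mode == "fixed":
        return MethodRanks(rank_by_method=dict(FIXED_RANKS), provenance="fixed")
    if mode != "empirical":
        raise ValueError(f"unknown rank mode {mode!r}")

    if isinstance(folds, int):
        from .evaluation import make_folds

        fold_partition = make_folds(table.y, folds, seed)
    else:
        fold_partition = folds
    grid = baseline_accuracy_grid(table, models, fold_partition, seed,
                                  mrmr_config, lasso_config, normalize_within_fold)
    best_lasso = max(grid[METHOD_LASSO].values())
    best_mrmr = max(grid[METHOD_MRMR].values())
    if best_mrmr > best_lasso:
        ranks = {METHOD_MRMR: 2, METHOD_LASSO: 1}
    else:  # ties keep the canonical order
        ranks = {METHOD_LASSO: 2, METHOD_MRMR: 1}
    return MethodRanks(rank_by_method=ranks, provenance="empirical",
                       diagnostics={"baseline_grid": grid})
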