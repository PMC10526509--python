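"""End-to-end orchestration: load, normalize, select, weight, sweep, pick.

One master seed drives everything; per-stage seeds are derived from it by
fixed offsets so stages are independently reproducible.  The stratified
outer-fold partition is generated once and shared by the selection and
evaluation phases.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .data_io import (
    KIND_CONTINUOUS,
    FeatureTable,
    load_feature_table,
    zscore_continuous,
)
from .evaluation import MODEL_ORDER, make_folds, run_sweep, select_best
from .report import SelectionReport, write_report
from .selectors import LassoConfig, MrmrConfig
from .weighting import (
    accumulate_weights,
    assign_ranks,
    baseline_accuracy_grid,
    candidate_sets,
    run_fold_selections,
)

log = logging.getLogger(__name__)

# fixed offsets deriving per-stage seeds from the master seed
_OFFSET_FOLDS = 0
_OFFSET_SELECT = 0  # run_fold_selections adds its own per-fold offsets
_OFFSET_EVAL = 7


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one run; echoed verbatim into the report."""

    seed: int
    input_path: str | None = None
    label_column: str = "Grade"
    positive_label: str = "GBM"
    n_outer_folds: int = 5
    rank_mode: str = "fixed"  # "fixed" or "empirical"
    models: tuple = MODEL_ORDER
    mrmr: MrmrConfig = field(default_factory=MrmrConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    normalize_per_fold: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2:
            raise ValueError("n_outer_folds must be >= 2")
        if self.seed is None:
            raise ValueError("a seed is mandatory; no silent nondeterminism")
        object.__setattr__(self, "models", tuple(self.models))

    def echo(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d


def _prepare(table: FeatureTable, config: RunConfig):
    """Normalize continuous features, or defer to per-fold statistics."""
    continuous = [n for n, k in zip(table.feature_names, table.feature_kinds)
                  if k == KIND_CONTINUOUS]
    if config.normalize_per_fold:
        # strict mode: training-split statistics are applied inside each fold
        return table, tuple(continuous)
    if continuous:
        table = zscore_continuous(table, continuous)
    return table, ()


def run_on_table(table: FeatureTable, config: RunConfig) -> SelectionReport:
    """Run the whole hybrid selection pipeline on an in-memory table."""
    t0 = time.perf_counter()
    table, within_fold = _prepare(table, config)
    partition = make_folds(table.y, config.n_outer_folds, config.seed + _OFFSET_FOLDS)
    log.info("stage=folds n=%d folds=%d (%.2fs)", table.n, config.n_outer_folds,
             time.perf_counter() - t0)

    ranks = assign_ranks(table, config.models, partition, config.seed,
                         mode=config.rank_mode, mrmr_config=config.mrmr,
                         lasso_config=config.lasso,
                         normalize_within_fold=within_fold)
    log.info("stage=ranks %s (%s)", ranks.rank_by_method, ranks.provenance)

    selections = run_fold_selections(table, partition, config.mrmr, config.lasso,
                                     seed=config.seed + _OFFSET_SELECT,
                                     normalize_within_fold=within_fold)
    ledger = accumulate_weights(selections, ranks, config.n_outer_folds,
                                feature_names=table.feature_names)
    log.info("stage=weights max_observed=%d/%d", ledger.max_observed,
             ledger.max_possible)

    candidates = candidate_sets(ledger)
    sweep = run_sweep(table, candidates, config.models, partition,
                      config.seed + _OFFSET_EVAL,
                      normalize_within_fold=within_fold)
    best = select_best(sweep)
    log.info("stage=best k=%d model=%s n_features=%d acc=%.3f (total %.2fs)",
             best.k, best.model, best.n_features, best.accuracy,
             time.perf_counter() - t0)

    return SelectionReport(
        best_k=best.k,
        best_model=best.model,
        selected_features=best.features,
        metrics=best.metrics,
        sweep=sweep,
        ledger=ledger,
        config_echo=config.echo(),
    )


def run_gradwise(config: RunConfig) -> SelectionReport:
    """Load the configured CSV, run the pipeline, optionally write outputs."""
    if config.input_path is None:
        raise ValueError("config.input_path is required")
    table = load_feature_table(config.input_path, config.label_column,
                               config.positive_label)
    report = run_on_table(table, config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        write_report(report, out / "report.json", format="json")
        write_report(report, out / "tables", format="csv-bundle")
        log.info("report written to %s", out)
    return report


def run_baselines(config: RunConfig, table: FeatureTable | None = None) -> dict:
    """Without-FS / LASSO-only / mRMR-only mean-accuracy grid (models x regimes)."""
    if table is None:
        if config.input_path is None:
            raise ValueError("config.input_path is required")
        table = load_feature_table(config.input_path, config.label_column,
                                   config.positive_label)
    table, within_fold = _prepare(table, config)
    partition = make_folds(table.y, config.n_outer_folds, config.seed + _OFFSET_FOLDS)
    return baseline_accuracy_grid(table, config.models, partition, config.seed,
                                  config.mrmr, config.lasso,
                                  normalize_within_fold=within_fold)
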