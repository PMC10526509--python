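"""Selection reports: the final audit trail of a run and its serializers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import MODEL_DISPLAY, EvalMetrics, SweepTable
from .weighting import WeightLedger


@dataclass(frozen=True)
class SelectionReport:
    """Winning configuration plus the full audit trail of a run.

    Invariants checked at construction: the selected features are exactly
    the ledger entries with weight >= ``best_k``, and the reported metrics
    match the sweep cell at (``best_k``, ``best_model``).
    """

    best_k: int
    best_model: str
    selected_features: tuple
    metrics: EvalMetrics
    sweep: SweepTable
    ledger: WeightLedger
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "selected_features", tuple(self.selected_features))
        expected = {f for f, w in self.ledger.weights.items() if w >= self.best_k}
        if set(self.selected_features) != expected:
            raise ValueError(
                "selected_features must be exactly the ledger entries with "
                f"weight >= {self.best_k}"
            )
        row = next((r for r in self.sweep.rows if r.k == self.best_k), None)
        if row is None:
            raise ValueError(f"no sweep row for k={self.best_k}")
        if self.best_model not in self.sweep.models:
            raise ValueError(f"model {self.best_model!r} not in sweep")
        if abs(float(row.acc_by_model[self.best_model]) - self.metrics.acc) > 1e-9:
            raise ValueError("metrics do not match the sweep cell at (best_k, best_model)")

    def to_dict(self) -> dict:
        return {
            "best_k": self.best_k,
            "best_model": self.best_model,
            "selected_features": list(self.selected_features),
            "metrics": self.metrics.to_dict(),
            "sweep": self.sweep.to_dict(),
            "ledger": self.ledger.to_dict(),
            "config_echo": self.config_echo,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionReport":
        return cls(
            best_k=int(d["best_k"]),
            best_model=d["best_model"],
            selected_features=tuple(d["selected_features"]),
            metrics=EvalMetrics.from_dict(d["metrics"]),
            sweep=SweepTable.from_dict(d["sweep"]),
            ledger=WeightLedger.from_dict(d["ledger"]),
            config_echo=d.get("config_echo", {}),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def write_report(report: SelectionReport, path, format: str = "json") -> None:
    """Write a report as a single JSON file or a directory of CSV files.

    The csv-bundle emits ``sweep.csv`` (one row per threshold k, one
    accuracy column per model, 3 decimals), ``ledger.csv`` (feature, weight,
    descending) and ``metrics.csv`` (the six-metric panel of the winning
    cell).
    """
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(report.to_json() + "\n")
    elif format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        report.sweep.to_dataframe().to_csv(path / "sweep.csv", index=False)
        with open(path / "ledger.csv", "w") as fh:
            fh.write("feature,weight\n")
            for f, w in report.ledger.sorted_items():
                fh.write(f"{f},{w}\n")
        with open(path / "metrics.csv", "w") as fh:
            fh.write("model,k,n_features,acc,auc,f1,pre,rec,spec\n")
            m = report.metrics
            fh.write(
                f"{MODEL_DISPLAY.get(report.best_model, report.best_model)},"
                f"{report.best_k},{len(report.selected_features)},"
                f"{m.acc:.3f},{m.auc:.3f},{m.f1:.3f},{m.pre:.3f},{m.rec:.3f},{m.spec:.3f}\n"
            )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> SelectionReport:
    """Read a JSON report written by :func:`write_report`."""
    return SelectionReport.from_dict(json.loads(Path(path).read_text()))
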