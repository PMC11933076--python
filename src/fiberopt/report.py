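"""Structured result bundle and its JSON serialization.

The bundle gathers everything a pipeline run produces — per-label feature
importance, surrogate evaluation metrics, inverse-design optima and the
aggregated per-feature optimal ranges — into one JSON document with stable
key order.  Every numeric leaf is stored at full precision together with a
"rounded" 4-decimal display string matching the convention of the original
study's result tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .schema import LABELS


class CompletenessError(ValueError):
    """A report section does not cover every label exactly once."""


@dataclass
class ImportanceEntry:
    feature: str
    rho: float | None
    relative_pct: float | None


@dataclass
class ImportanceReport:
    """Spearman feature importance for one label."""

    label: str
    entries: list[ImportanceEntry]
    feature_set: tuple[str, ...]


@dataclass
class EvaluationMetrics:
    """MAE / MSE / RMSE in original label units."""

    mae: float
    mse: float
    rmse: float

    def __post_init__(self) -> None:
        if min(self.mae, self.mse, self.rmse) < 0:
            raise ValueError("error metrics must be non-negative")
        if abs(self.rmse - self.mse**0.5) > 1e-9 * max(1.0, self.rmse):
            raise ValueError("rmse must equal sqrt(mse)")
        # power-mean inequality; holds for any single evaluation set
        if self.mae > self.rmse * (1 + 1e-12) + 1e-15:
            raise ValueError("mae cannot exceed rmse")


@dataclass
class OptimizationResult:
    """Inverse-design outcome for one label."""

    label: str
    direction: str
    x_opt: dict[str, float]
    predicted_value: float
    swarm_best_history: list[float] = field(default_factory=list)


@dataclass
class OptimalRangeTable:
    """Per fixed feature: (range_min, range_max) across the four optima."""

    ranges: dict[str, tuple[float, float]]
    flagged: dict[str, str] = field(default_factory=dict)


@dataclass
class ReportBundle:
    importance: dict[str, ImportanceReport]
    metrics: dict[str, EvaluationMetrics]
    optima: dict[str, OptimizationResult]
    ranges: OptimalRangeTable
    provenance: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        for section_name, section in (
            ("importance", self.importance),
            ("metrics", self.metrics),
            ("optima", self.optima),
        ):
            if tuple(sorted(section)) != tuple(sorted(LABELS)):
                raise CompletenessError(
                    f"section {section_name!r} must cover every label exactly once; "
                    f"got {sorted(section)}"
                )


def _num(x: float) -> dict[str, Any]:
    return {"value": float(x), "rounded": f"{float(x):.4f}"}


def _bundle_to_dict(bundle: ReportBundle) -> dict[str, Any]:
    doc: dict[str, Any] = {"importance": {}, "metrics": {}, "optima": {}, "ranges": {}}
    for label in LABELS:
        rep = bundle.importance[label]
        doc["importance"][label] = {
            "feature_set": list(rep.feature_set),
            "entries": [
                {
                    "feature": e.feature,
                    "rho": None if e.rho is None else _num(e.rho),
                    "relative_pct": None
                    if e.relative_pct is None
                    else _num(e.relative_pct),
                }
                for e in rep.entries
            ],
        }
        m = bundle.metrics[label]
        doc["metrics"][label] = {
            "mae": _num(m.mae),
            "mse": _num(m.mse),
            "rmse": _num(m.rmse),
        }
        opt = bundle.optima[label]
        doc["optima"][label] = {
            "direction": opt.direction,
            "x_opt": {k: _num(v) for k, v in opt.x_opt.items()},
            "predicted_value": _num(opt.predicted_value),
            "swarm_best_history": [float(v) for v in opt.swarm_best_history],
        }
    doc["ranges"] = {
        "ranges": {k: [_num(lo), _num(hi)] for k, (lo, hi) in bundle.ranges.ranges.items()},
        "flagged": dict(bundle.ranges.flagged),
    }
    doc["provenance"] = bundle.provenance
    return doc


def write_report(bundle: ReportBundle, path: str | Path) -> None:
    """Serialize a complete bundle to JSON with stable key order."""
    bundle.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_bundle_to_dict(bundle), indent=1, sort_keys=False))


def read_report(path: str | Path) -> ReportBundle:
    """Parse a bundle written by :func:`write_report`."""
    doc = json.loads(Path(path).read_text())
    importance = {
        label: ImportanceReport(
            label=label,
            feature_set=tuple(sec["feature_set"]),
            entries=[
                ImportanceEntry(
                    feature=e["feature"],
                    rho=None if e["rho"] is None else e["rho"]["value"],
                    relative_pct=None
                    if e["relative_pct"] is None
                    else e["relative_pct"]["value"],
                )
                for e in sec["entries"]
            ],
        )
        for label, sec in doc["importance"].items()
    }
    metrics = {
        label: EvaluationMetrics(
            mae=sec["mae"]["value"], mse=sec["mse"]["value"], rmse=sec["rmse"]["value"]
        )
        for label, sec in doc["metrics"].items()
    }
    optima = {
        label: OptimizationResult(
            label=label,
            direction=sec["direction"],
            x_opt={k: v["value"] for k, v in sec["x_opt"].items()},
            predicted_value=sec["predicted_value"]["value"],
            swarm_best_history=list(sec["swarm_best_history"]),
        )
        for label, sec in doc["optima"].items()
    }
    ranges = OptimalRangeTable(
        ranges={
            k: (lo["value"], hi["value"])
            for k, (lo, hi) in doc["ranges"]["ranges"].items()
        },
        flagged=dict(doc["ranges"]["flagged"]),
    )
    bundle = ReportBundle(
        importance=importance,
        metrics=metrics,
        optima=optima,
        ranges=ranges,
        provenance=doc.get("provenance", {}),
    )
    bundle.validate()
    return bundle
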