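"""End-to-end orchestration: generate/load -> preprocess -> importance ->
train/evaluate -> inverse-optimize -> report.

A :class:`PipelineConfig` (readable from a YAML mapping) captures every knob;
defaults reproduce the original analysis's printed settings (per-label SVR
hyperparameters, PSO coefficients, 80/20 split).  Each stage writes its
artifact to the output directory so stages can be re-run and inspected
independently; the whole run is a pure function of the config's seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import published
from .dataset import NanofiberDataset, load_dataset, write_dataset
from .importance import importance_report
from .optimize import ParticleSwarmConfig, aggregate_optimal_ranges, optimize_label
from .preprocessing import PreprocessedData, preprocess_pipeline
from .report import ReportBundle, write_report
from .schema import DIRECTIONS, LABELS
from .surrogate import (
    SurrogateModel,
    SvrHyperparams,
    default_hyperparams,
    evaluate,
    split_dataset,
    train_svr,
)
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("fiberopt")


class PipelineConfigError(ValueError):
    """A config value is missing, mistyped or out of range."""


@dataclass
class PipelineConfig:
    dataset_path: str | None = None  # None -> generate synthetically
    output_dir: str = "results"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    svr: dict[str, SvrHyperparams] = field(
        default_factory=lambda: {lbl: default_hyperparams(lbl) for lbl in LABELS}
    )
    split_seed: int = 42
    test_fraction: float = 0.2
    pso: ParticleSwarmConfig = field(default_factory=ParticleSwarmConfig)
    imputation_tol: float = 1e-5
    imputation_max_iter: int = 500
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise PipelineConfigError(f"cannot parse config: {exc}") from exc
        if not isinstance(doc, dict):
            raise PipelineConfigError("config root must be a mapping")
        cfg = cls()
        try:
            for key in ("dataset_path", "output_dir", "split_seed", "test_fraction",
                        "imputation_tol", "imputation_max_iter", "log_level"):
                if key in doc:
                    setattr(cfg, key, doc[key])
            if "synthetic" in doc:
                cfg.synthetic = SyntheticConfig(**doc["synthetic"])
            if "svr" in doc:
                for lbl, hp in doc["svr"].items():
                    if lbl not in LABELS:
                        raise PipelineConfigError(f"svr: unknown label {lbl!r}")
                    cfg.svr[lbl] = SvrHyperparams(**hp)
            if "pso" in doc:
                cfg.pso = ParticleSwarmConfig(**doc["pso"])
        except (TypeError, ValueError) as exc:
            raise PipelineConfigError(str(exc)) from exc
        if not 0 < cfg.test_fraction < 1:
            raise PipelineConfigError("test_fraction must be in (0, 1)")
        return cfg


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the four stages in order and write all artifacts.

    Returns the assembled :class:`ReportBundle`; raises with the failing
    stage's name on any stage error.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = _stage("dataset")
    try:
        if cfg.dataset_path is not None:
            ds = load_dataset(cfg.dataset_path)
        else:
            ds, _truth = generate_dataset(cfg.synthetic)
            write_dataset(ds, out / "dataset.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'dataset' failed: {exc}") from exc
    _done("dataset", t0)

    t0 = _stage("preprocess")
    try:
        pre: PreprocessedData = preprocess_pipeline(
            ds, tol=cfg.imputation_tol, max_iter=cfg.imputation_max_iter
        )
        pre.state.to_json(out / "transform.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    _done("preprocess", t0)

    t0 = _stage("importance")
    try:
        importance = {
            lbl: importance_report(pre.features, pre.labels, lbl) for lbl in LABELS
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'importance' failed: {exc}") from exc
    _done("importance", t0)

    t0 = _stage("train")
    try:
        models: dict[str, SurrogateModel] = {}
        metrics = {}
        train_idx, test_idx = split_dataset(
            ds.n_rows, test_fraction=cfg.test_fraction, seed=cfg.split_seed
        )
        for lbl in LABELS:
            model = train_svr(
                pre.features.iloc[train_idx],
                pre.labels[lbl].iloc[train_idx],
                lbl,
                cfg.svr[lbl],
            )
            models[lbl] = model
            metrics[lbl] = evaluate(
                model,
                pre.features.iloc[test_idx],
                pre.labels[lbl].iloc[test_idx],
                pre.state,
            )
            model.to_json(out / f"model_{lbl}.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc
    _done("train", t0)

    t0 = _stage("optimize")
    try:
        optima = {
            lbl: optimize_label(models[lbl], pre.state, cfg.pso, DIRECTIONS[lbl])
            for lbl in LABELS
        }
        ranges = aggregate_optimal_ranges(optima)
    except Exception as exc:
        raise RuntimeError(f"stage 'optimize' failed: {exc}") from exc
    _done("optimize", t0)

    bundle = ReportBundle(
        importance=importance,
        metrics=metrics,
        optima=optima,
        ranges=ranges,
        provenance={
            "preprocessing_order": "box-cox -> soft-impute -> min-max",
            "labels_imputed": False,
            "imputation_converged": bool(pre.imputation.converged),
            "imputation_iterations": int(pre.imputation.n_iter),
            "split_seed": cfg.split_seed,
            "pso": {
                "c1": cfg.pso.c1,
                "c2": cfg.pso.c2,
                "omega": cfg.pso.omega,
                "n_particles": cfg.pso.n_particles,
                "n_iters": cfg.pso.n_iters,
                "seed": cfg.pso.seed,
            },
        },
    )
    write_report(bundle, out / "report.json")
    _write_tables(bundle, out)
    return bundle


def _write_tables(bundle: ReportBundle, out: Path) -> None:
    """Optima (features x labels) and ranges (feature, min, max) CSVs."""
    import pandas as pd

    feats: list[str] = []
    for lbl in LABELS:
        for f in bundle.optima[lbl].x_opt:
            if f not in feats:
                feats.append(f)
    table = pd.DataFrame(
        {lbl: [bundle.optima[lbl].x_opt.get(f) for f in feats] for lbl in LABELS},
        index=feats,
    )
    table.index.name = "feature"
    table.to_csv(out / "optima.csv")

    rng = pd.DataFrame(
        [(f, lo, hi) for f, (lo, hi) in bundle.ranges.ranges.items()],
        columns=["feature", "range_min", "range_max"],
    )
    rng.to_csv(out / "optimal_ranges.csv", index=False)


def reported_range_check() -> dict[str, bool]:
    """Strict min/max aggregation of the originally reported optima versus
    the originally reported ranges (one known discrepancy is flagged False)."""
    return published.check_reported_consistency()
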