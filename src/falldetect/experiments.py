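"""End-to-end experiment drivers.

Three experiments mirror the study design: a binary fall-vs-ADL comparison
of the five classifiers at one sampling rate, a sweep of that comparison
across the sampling-rate grid, and the four-class fall-phase task at 50 Hz.
Fold assignments are computed once per experiment and shared across rates
and algorithms so that comparisons are paired.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import IMURecord, PHASE_CLASSES
from .evaluation import (
    ALGORITHMS,
    EvaluationReport,
    FoldSplit,
    cross_validate,
    make_subject_folds,
)
from .features import extract_features
from .io import ActivityCatalog, read_manifest, read_sisfall_record
from .phases import build_multiclass_dataset
from .preprocess import DEFAULT_RATE_GRID, decimate, prepare_records
from .synthetic import SyntheticConfig, iter_cohort_records

logger = logging.getLogger(__name__)

METRIC_KEYS = ("sensitivity", "specificity", "accuracy", "f1", "auroc")


@dataclass
class RunConfig:
    """Everything an experiment needs: data source, rates, algorithms, seeds."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    data_root: Path | None = None
    manifest_path: Path | None = None
    rate: float = 50.0
    rates: tuple[float, ...] = DEFAULT_RATE_GRID
    algorithms: tuple[str, ...] = ALGORITHMS
    k: int = 5
    seed: int = 0
    normalize_scope: str = "train"
    out_dir: Path | None = None

    def source_rate(self) -> float:
        return self.synthetic.sampling_rate

    def validate(self) -> None:
        problems = []
        for r in (*self.rates, self.rate):
            if r <= 0 or abs(self.source_rate() / r - round(self.source_rate() / r)) > 1e-9:
                problems.append(f"rate {r} Hz does not divide source rate")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                problems.append(f"unknown algorithm {a!r}")
        if self.normalize_scope not in ("train", "global"):
            problems.append(f"bad normalize_scope {self.normalize_scope!r}")
        if self.k < 2:
            problems.append("k must be >= 2")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))


def load_raw_records(cfg: RunConfig, catalog: ActivityCatalog) -> list[IMURecord]:
    """Load the cohort: from disk when a data root is configured, otherwise
    generated in memory from the synthetic config."""
    if cfg.data_root is not None:
        from .io import scan_manifest

        manifest = (
            read_manifest(cfg.manifest_path)
            if cfg.manifest_path is not None
            else scan_manifest(cfg.data_root, catalog)
        )
        return [
            read_sisfall_record(row.path, catalog, sampling_rate=cfg.source_rate())
            for row in manifest.itertuples(index=False)
        ]
    return list(iter_cohort_records(cfg.synthetic, catalog))


def _shared_folds(cfg: RunConfig, records: Sequence[IMURecord]) -> FoldSplit:
    return make_subject_folds([r.subject_id for r in records], k=cfg.k, seed=cfg.seed)


def _write_report(report: EvaluationReport, out_dir: Path | None, name: str) -> None:
    if out_dir is None:
        return
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_json(out_dir / f"{name}.json")


def _write_run_manifest(cfg: RunConfig, experiment: str) -> None:
    if cfg.out_dir is None:
        return
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "experiment": experiment,
        "package_version": _pkg_version("falldetect"),
        "config": {
            **{
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(cfg).items()
                if k != "synthetic"
            },
            "synthetic": dataclasses.asdict(cfg.synthetic),
        },
    }
    (cfg.out_dir / f"{experiment}_run.json").write_text(
        json.dumps(payload, indent=2, default=list) + "\n"
    )


def run_binary(
    cfg: RunConfig, catalog: ActivityCatalog | None = None
) -> dict[str, EvaluationReport]:
    """Fall-vs-ADL cross-validation of every configured algorithm at one rate."""
    cfg.validate()
    catalog = catalog or ActivityCatalog.default()
    raw = load_raw_records(cfg, catalog)
    prepared = prepare_records(raw, catalog, cfg.rate)
    folds = _shared_folds(cfg, prepared)
    feats = extract_features(prepared)
    reports = {}
    for name in cfg.algorithms:
        report = cross_validate(
            feats,
            name,
            folds,
            label_col="label",
            seed=cfg.seed,
            normalize_scope=cfg.normalize_scope,
            classes=("ADL", "FALL"),
        )
        report.config["rate_hz"] = cfg.rate
        reports[name] = report
        _write_report(report, cfg.out_dir, f"binary_{name}_{int(cfg.rate)}hz")
        logger.info(
            "binary %s @ %g Hz: accuracy %.4f", name, cfg.rate, report.mean("accuracy")
        )
    _write_run_manifest(cfg, "binary")
    return reports


def run_rate_sweep(
    cfg: RunConfig, catalog: ActivityCatalog | None = None, plot: bool = True
) -> pd.DataFrame:
    """Cross-validate every (rate, algorithm) pair of the grid.

    Returns a long-format frame with one row per pair and one column per
    metric mean; when an output directory is set, also writes one
    rates-by-algorithms CSV per metric and a metrics-vs-rate figure.
    """
    cfg.validate()
    catalog = catalog or ActivityCatalog.default()
    raw = load_raw_records(cfg, catalog)
    # equalize durations once at the source rate, then decimate per grid rate
    base = prepare_records(raw, catalog, cfg.source_rate())
    del raw
    folds = _shared_folds(cfg, base)
    rows = []
    for rate in cfg.rates:
        feats = extract_features([decimate(r, rate) for r in base])
        for name in cfg.algorithms:
            report = cross_validate(
                feats,
                name,
                folds,
                label_col="label",
                seed=cfg.seed,
                normalize_scope=cfg.normalize_scope,
                classes=("ADL", "FALL"),
            )
            summary = report.summary()
            rows.append(
                {
                    "rate_hz": rate,
                    "algorithm": name,
                    "n_records": len(feats),
                    **{m: summary[m]["mean"] for m in METRIC_KEYS if m in summary},
                }
            )
            logger.info(
                "sweep %s @ %g Hz: accuracy %.4f", name, rate, summary["accuracy"]["mean"]
            )
    table = pd.DataFrame(rows)
    if cfg.out_dir is not None:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(cfg.out_dir / "sweep_long.csv", index=False)
        for metric in METRIC_KEYS:
            if metric in table:
                pivot = table.pivot(index="rate_hz", columns="algorithm", values=metric)
                pivot.to_csv(cfg.out_dir / f"sweep_{metric}.csv")
        if plot:
            _plot_sweep(table, cfg.out_dir / "sweep_metrics.png")
    _write_run_manifest(cfg, "sweep")
    return table


def _plot_sweep(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [m for m in METRIC_KEYS if m in table.columns]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2), sharey=True)
    for ax, metric in zip(np.atleast_1d(axes), metrics):
        for name, grp in table.groupby("algorithm"):
            ax.plot(grp["rate_hz"], grp[metric], marker="o", label=name)
        ax.set_xscale("log")
        ax.set_xlabel("sampling rate [Hz]")
        ax.set_title(metric)
    axes_flat = np.atleast_1d(axes)
    axes_flat[0].set_ylabel("score")
    axes_flat[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_multiclass(
    cfg: RunConfig, catalog: ActivityCatalog | None = None
) -> dict[str, EvaluationReport]:
    """Four-class fall-phase cross-validation (ADL / pre-fall / impact /
    post-fall) at the configured rate, 50 Hz by default."""
    cfg.validate()
    catalog = catalog or ActivityCatalog.default()
    raw = load_raw_records(cfg, catalog)
    prepared = prepare_records(raw, catalog, cfg.rate)
    folds = _shared_folds(cfg, prepared)
    feats, phase_report = build_multiclass_dataset(prepared)
    if phase_report["empty_phases"]:
        logger.warning("%d empty phases skipped", phase_report["empty_phases"])
    reports = {}
    for name in cfg.algorithms:
        report = cross_validate(
            feats,
            name,
            folds,
            label_col="phase",
            seed=cfg.seed,
            normalize_scope=cfg.normalize_scope,
            classes=PHASE_CLASSES,
        )
        report.config["rate_hz"] = cfg.rate
        report.config["phase_report"] = phase_report
        reports[name] = report
        _write_report(report, cfg.out_dir, f"multiclass_{name}_{int(cfg.rate)}hz")
        logger.info(
            "multiclass %s @ %g Hz: macro F1 %.4f", name, cfg.rate, report.mean("f1")
        )
    _write_run_manifest(cfg, "multiclass")
    return reports

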