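"""End-to-end orchestration: simulate/extract -> select -> evaluate.

One :class:`PipelineConfig` drives a full run: a cohort source (exactly
one of synthetic config, feature-table CSV, or GM-map manifest), the
classifier/fold settings, and the evaluation options.  Every stage
persists its artifact under the output directory and the run manifest
records config, seed derivations and wall times, so a run can be
reproduced bit-identically and every reported number traced to a file.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .evaluation import accuracy, roc_report, thi_volume_correlation
from .fscore import compute_fscore, fscore_frame
from .roi import default_catalogue, extract_features, load_catalogue, load_gm_map
from .selection import (
    ClassifierConfig,
    make_fold_plan,
    pooled_scored_subjects,
    run_nested_selection,
)
from .tables import FeatureTable, read_table, write_table
from .util import derive_seed

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "replicate_study",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one cohort source must be set."""

    output_dir: Path
    master_seed: int
    cohort: CohortConfig | None = None
    table_path: Path | None = None
    gm_manifest: Path | None = None
    catalogue_path: Path | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    k_folds: int = 5
    floating: bool = False
    age_control: bool = False
    correlations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.cohort, self.table_path, self.gm_manifest)
            if s is not None
        ]
        if len(sources) != 1:
            raise ConfigError(
                "exactly one cohort source (cohort config, table path, or "
                f"GM manifest) must be given; got {len(sources)}"
            )
        if self.master_seed is None:
            raise ConfigError("master_seed is mandatory")
        self.output_dir = Path(self.output_dir)

    def snapshot(self) -> dict:
        d = {
            "version": __version__,
            "master_seed": self.master_seed,
            "k_folds": self.k_folds,
            "floating": self.floating,
            "age_control": self.age_control,
            "correlations": [list(c) for c in self.correlations],
            "classifier": asdict(self.classifier),
            "output_dir": str(self.output_dir),
        }
        if self.cohort is not None:
            c = asdict(self.cohort)
            c["thi_model"] = (
                asdict(self.cohort.thi_model)
                if self.cohort.thi_model is not None
                else None
            )
            d["cohort"] = c
        if self.table_path is not None:
            d["table_path"] = str(self.table_path)
        if self.gm_manifest is not None:
            d["gm_manifest"] = str(self.gm_manifest)
            d["catalogue_path"] = (
                str(self.catalogue_path) if self.catalogue_path else None
            )
        return d


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    stage_paths: dict
    stage_seconds: dict
    metrics: dict

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "seeds": self.seeds,
                    "stage_paths": self.stage_paths,
                    "stage_seconds": {
                        k: round(v, 3) for k, v in self.stage_seconds.items()
                    },
                    "metrics": self.metrics,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _acquire_table(config: PipelineConfig) -> FeatureTable:
    if config.cohort is not None:
        cohort = replace(
            config.cohort, seed=derive_seed(config.master_seed, "cohort")
        )
        return generate_cohort(cohort)
    if config.table_path is not None:
        try:
            return read_table(config.table_path)
        except Exception as err:
            raise DataError(f"loading {config.table_path}: {err}") from err
    manifest = pd.read_csv(config.gm_manifest)
    required = {"subject_id", "group", "map_path"}
    if not required <= set(manifest.columns):
        raise DataError(
            f"GM manifest needs columns {sorted(required)}, "
            f"found {list(manifest.columns)}"
        )
    catalogue = (
        load_catalogue(config.catalogue_path)
        if config.catalogue_path
        else default_catalogue()
    )
    subjects = []
    base = Path(config.gm_manifest).parent
    for row in manifest.to_dict("records"):
        p = Path(row["map_path"])
        gm = load_gm_map(p if p.is_absolute() else base / p)
        subjects.append((row, gm))
    return extract_features(subjects, catalogue)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, persisting intermediates and a run manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    times: dict[str, float] = {}
    seeds = {
        "master": config.master_seed,
        "cohort": derive_seed(config.master_seed, "cohort"),
        "outer_folds": derive_seed(config.master_seed, "outer"),
    }

    t0 = time.perf_counter()
    table = _acquire_table(config)
    table_path = out / "feature_table.csv"
    write_table(table, table_path)
    paths["feature_table"] = str(table_path)
    times["cohort"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fs = compute_fscore(table.volumes, table.labels)
    fs_path = out / "fscores.csv"
    fscore_frame(fs, table.region_names).to_csv(fs_path, index=False)
    paths["fscores"] = str(fs_path)
    times["fscore"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        plan = make_fold_plan(
            table.n_patients, table.n_controls, config.k_folds,
            seeds["outer_folds"],
        )
    except ValueError as err:
        raise DataError(str(err)) from err
    result = run_nested_selection(
        table, config.classifier, plan,
        floating=config.floating, age_control=config.age_control,
    )
    sel_path = out / "selection.json"
    sel_path.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
    paths["selection"] = str(sel_path)
    times["selection"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scored = pooled_scored_subjects(table, result)
    roc = roc_report(scored)
    roc_path = out / "roc_points.csv"
    pd.DataFrame(
        {"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}
    ).to_csv(roc_path, index=False)
    paths["roc_points"] = str(roc_path)
    metrics = {
        "n_subjects": table.n_subjects,
        "n_patients": table.n_patients,
        "n_controls": table.n_controls,
        "mean_train_accuracy": result.mean_train_accuracy,
        "mean_test_accuracy": result.mean_test_accuracy,
        "pooled_accuracy": accuracy(scored),
        "auc": roc.auc,
        "consensus_features": result.consensus_features,
        "per_fold": [
            {
                "train_accuracy": f.train_accuracy,
                "test_accuracy": f.test_accuracy,
                "n_selected": len(f.selected_features),
                "c": f.c,
                "gamma": f.gamma,
            }
            for f in result.folds
        ],
    }
    if config.correlations:
        rows = []
        for band, region in config.correlations:
            try:
                rep = thi_volume_correlation(table, band, region)
                rows.append(asdict(rep))
            except (ValueError, KeyError) as err:
                rows.append(
                    {"band": band, "region": region, "error": str(err)}
                )
        corr_path = out / "correlations.csv"
        pd.DataFrame(rows).to_csv(corr_path, index=False)
        paths["correlations"] = str(corr_path)
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    paths["metrics"] = str(metrics_path)
    times["evaluation"] = time.perf_counter() - t0

    manifest = RunManifest(config.snapshot(), seeds, paths, times, metrics)
    manifest.write(out / "manifest.json")
    return manifest


def replicate_study(
    config: PipelineConfig, n_replicates: int
) -> dict:
    """Repeat the synthetic pipeline over derived seeds and aggregate.

    Returns per-replicate metrics (DataFrame), a mean +/- SD summary, and
    pooled per-region selection frequencies.  Requires a synthetic
    cohort source.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if config.cohort is None:
        raise ConfigError("replicate_study needs a synthetic cohort source")
    rows = []
    freqs: dict[str, int] = {}
    for i in range(n_replicates):
        rep_seed = derive_seed(config.master_seed, "replicate", i)
        rep_config = replace(
            config,
            master_seed=rep_seed,
            output_dir=config.output_dir / f"replicate_{i:02d}",
        )
        manifest = run_pipeline(rep_config)
        m = manifest.metrics
        rows.append(
            {
                "replicate": i,
                "seed": rep_seed,
                "train_accuracy": m["mean_train_accuracy"],
                "test_accuracy": m["mean_test_accuracy"],
                "auc": m["auc"],
                "mean_n_selected": float(
                    np.mean([f["n_selected"] for f in m["per_fold"]])
                ),
            }
        )
        sel_path = Path(manifest.stage_paths["selection"])
        sel = json.loads(sel_path.read_text())
        for name, count in sel["selection_frequencies"].items():
            freqs[name] = freqs.get(name, 0) + count
    df = pd.DataFrame(rows)
    summary = {
        "n_replicates": n_replicates,
        "train_accuracy_mean": float(df["train_accuracy"].mean()),
        "train_accuracy_sd": float(df["train_accuracy"].std(ddof=1))
        if n_replicates > 1
        else 0.0,
        "test_accuracy_mean": float(df["test_accuracy"].mean()),
        "test_accuracy_sd": float(df["test_accuracy"].std(ddof=1))
        if n_replicates > 1
        else 0.0,
        "auc_mean": float(df["auc"].mean()),
        "auc_sd": float(df["auc"].std(ddof=1)) if n_replicates > 1 else 0.0,
        "mean_n_selected": float(df["mean_n_selected"].mean()),
    }
    config.output_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(config.output_dir / "replicates.csv", index=False)
    (config.output_dir / "replicate_summary.json").write_text(
        json.dumps(
            {
                "summary": summary,
                "selection_frequencies": dict(
                    sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
                ),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {
        "replicates": df,
        "summary": summary,
        "selection_frequencies": dict(
            sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
    }
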