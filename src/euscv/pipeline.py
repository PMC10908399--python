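"""Experiment orchestration: configuration, seeding, file formats.

``run_experiment`` composes the full pipeline — simulate a cohort, rate it
with the synthetic endoscopist panel, divide patients by a factor in one
or both manners, run the 20-session cross-validation per division,
evaluate, and write the result tables — reproducibly from one config and
one global seed.  Per-stage seeds are derived from the global seed plus
the stage name (see :mod:`euscv._seeding`), so adding a stage never
perturbs earlier stages' randomness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeding import derive_seed
from .classifier import CVResult, RandomProjectionExtractor, TrainConfig, run_cross_validation
from .cohort import (
    CohortSpec,
    CovariateParams,
    SpecValidationError,
    cohort_metadata,
    default_crop_box,
    generate_cohort,
    simulate_endoscopists,
)
from .evaluation import aggregate_folds, cohort_table, compare_fold_scores, confusion_metrics, METRIC_NAMES
from .imaging import AugmentConfig, FrameStore, SamplingConfig
from .splits import divide, order_patients, write_division

__all__ = [
    "RunConfig",
    "ExperimentRecord",
    "run_experiment",
    "read_metadata",
    "write_results",
    "load_config",
    "save_config",
    "evaluate_cv",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to re-run an experiment."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    factor: str = "EDA"
    modes: tuple[str, ...] = ("ordered", "balanced")
    k: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)
    extractor_seed: int = 0
    extractor_dim: int = 128
    seed: int = 0
    out_dir: str = "results/experiment"

    def validate(self) -> None:
        self.cohort.validate()
        self.train.validate()
        if self.factor.upper() not in ("CHR", "AGE", "BMI", "SAI", "EDA"):
            raise ValueError(f"factor: unknown factor {self.factor!r}")
        for m in self.modes:
            if m not in ("ordered", "balanced"):
                raise ValueError(f"modes: unknown mode {m!r}")
        if self.k < 3:
            raise ValueError("k: must be >= 3")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


_REQUIRED_TOP = ["cohort", "factor", "modes", "k", "train", "seed", "out_dir"]


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; errors name the offending field.

    Round-trips losslessly with :func:`save_config`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    for key in _REQUIRED_TOP:
        if key not in raw:
            raise SpecValidationError(key, "missing required config field")

    def _tupled(d, *keys):
        for k in keys:
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return d

    cd = _tupled(dict(raw["cohort"]), "videos_per_patient", "frames_per_video", "min_crop")
    if "covariate_params" in cd:
        cp = _tupled(dict(cd["covariate_params"]), "age_range", "bmi_range", "alcohol_probs")
        cd["covariate_params"] = CovariateParams(**cp)
    td = dict(raw["train"])
    if "sampling" in td:
        sd = dict(td["sampling"])
        if "augment" in sd:
            sd["augment"] = AugmentConfig(**sd["augment"])
        td["sampling"] = SamplingConfig(**sd)
    config = RunConfig(
        cohort=CohortSpec(**cd),
        factor=raw["factor"],
        modes=tuple(raw["modes"]),
        k=int(raw["k"]),
        train=TrainConfig(**td),
        extractor_seed=int(raw.get("extractor_seed", 0)),
        extractor_dim=int(raw.get("extractor_dim", 128)),
        seed=int(raw["seed"]),
        out_dir=str(raw["out_dir"]),
    )
    config.validate()
    return config


_METADATA_COLUMNS = [
    "patient_id",
    "label",
    "age_years",
    "bmi",
    "alcohol_g_per_day",
    "alcohol_category",
    "session_date",
    "eda_score",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient-metadata CSV.

    Rejects missing columns, duplicate patient ids, and labels outside
    {0, 1} (naming the CSV line, header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns and c != "eda_score"]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate patient_id: {dup.iloc[0]!r}")
    bad = df.index[~df["label"].isin((0, 1))]
    if len(bad):
        raise ValueError(f"label outside {{0,1}} at line {int(bad[0]) + 2}")
    return df


@dataclass(frozen=True)
class ExperimentRecord:
    """Self-describing experiment output."""

    config: RunConfig
    metadata: pd.DataFrame
    cohort_summary: pd.DataFrame
    results: pd.DataFrame  # one row per (mode, fold)
    summary: dict
    cv_results: dict  # mode -> CVResult
    out_dir: Path


def evaluate_cv(cv: CVResult, threshold: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Per-fold confusion metrics (patient-level scores) and their mean."""
    fold_metrics = [confusion_metrics(f.scores, f.labels, threshold) for f in cv.folds]
    rows = []
    for f, m in zip(cv.folds, fold_metrics):
        row = {"fold": f.test_group, **m.as_dict(), "n_patients": len(f.patient_ids)}
        rows.append(row)
    agg = aggregate_folds(fold_metrics)
    return pd.DataFrame(rows), agg


def write_results(record: ExperimentRecord, out_dir: str | Path | None = None) -> Path:
    """Write the experiment tables (floats at 6 significant digits)."""
    out = Path(out_dir or record.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record.metadata.to_csv(out / "metadata.csv", index=False, float_format="%.6g")
    record.cohort_summary.to_csv(out / "cohort_table.csv", index=False, float_format="%.6g")
    record.results.to_csv(out / "fold_metrics.csv", index=False, float_format="%.6g")
    (out / "summary.json").write_text(json.dumps(record.summary, indent=2, sort_keys=True))
    save_config(record.config, out / "config.yaml")
    return out


def run_experiment(config: RunConfig, write: bool = True) -> ExperimentRecord:
    """Run the full pipeline for one factor (both division manners by
    default) and return a self-describing record.

    With the random-projection extractor the whole computation is a pure
    function of the config, so repeated runs write identical files.
    """
    config.validate()
    out = Path(config.out_dir)

    cohort = generate_cohort(config.cohort)
    simulate_endoscopists(
        cohort,
        n_experts=config.cohort.n_experts,
        n_novices=config.cohort.n_novices,
        seed=derive_seed(config.seed, "endoscopists"),
    )
    metadata = cohort_metadata(cohort)
    summary_table = cohort_table(metadata)

    crop = default_crop_box(config.cohort.frame_height, config.cohort.frame_width)
    store = FrameStore.from_cohort(cohort, crop_box=crop)
    extractor = RandomProjectionExtractor(
        seed=config.extractor_seed, output_dim=config.extractor_dim
    )

    ranked = order_patients(cohort, config.factor)
    all_rows = []
    summary: dict = {"factor": config.factor, "version": __version__, "modes": {}}
    cv_results: dict[str, CVResult] = {}
    per_mode_folds: dict[str, pd.DataFrame] = {}
    for mode in config.modes:
        division = divide(ranked, config.k, mode, factor=config.factor)
        if write:
            out.mkdir(parents=True, exist_ok=True)
            write_division(division, out / f"division_{config.factor}_{mode}.csv")
        cv = run_cross_validation(
            store, division, extractor, config.train,
            seed=derive_seed(config.seed, "cv", config.factor, mode),
        )
        fold_df, agg = evaluate_cv(cv)
        fold_df.insert(0, "mode", mode)
        fold_df.insert(0, "factor", config.factor)
        all_rows.append(fold_df)
        per_mode_folds[mode] = fold_df
        summary["modes"][mode] = agg
        cv_results[mode] = cv

    if set(config.modes) == {"ordered", "balanced"}:
        summary["ordered_vs_balanced_p"] = {
            name: compare_fold_scores(
                per_mode_folds["ordered"][name].to_numpy(),
                per_mode_folds["balanced"][name].to_numpy(),
            )
            for name in METRIC_NAMES
        }

    record = ExperimentRecord(
        config=config,
        metadata=metadata,
        cohort_summary=summary_table,
        results=pd.concat(all_rows, ignore_index=True),
        summary=summary,
        cv_results=cv_results,
        out_dir=out,
    )
    if write:
        write_results(record)
    return record
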