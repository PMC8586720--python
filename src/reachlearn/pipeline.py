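"""Orchestration and I/O: generation -> fitting -> selection -> inference.

The on-disk layout of a run is plain text: the canonical trial-table CSV
(one row per trial) plus a per-direction initial-exposure sidecar CSV, a
JSON manifest with the full configuration and seeds, fits and the selection
report as JSON.  Trial indices are 1-based in files (trial 0 is the
initial-exposure trial); directions are 1..6.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    SubjectTaskSlice,
    SyntheticDataset,
    generate_cohort,
)
from .fitting import FitConfig, FitResult, exclude_gain_zero, fit_all
from .models import ModelParams, ModelSpec, TrialSchedule
from .selection import CVReport, cross_validate, parameter_inference

__all__ = [
    "RunConfig",
    "SchemaError",
    "TRIAL_COLUMNS",
    "read_trial_table",
    "write_trial_table",
    "run_full_analysis",
]

log = logging.getLogger("reachlearn")

TRIAL_COLUMNS = [
    "subject", "task", "trial", "direction", "vision",
    "ea_gain", "ea_offset", "max_error_cm",
]


class SchemaError(ValueError):
    """Raised when an input table violates the trial-table schema."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run.

    Every stage's random stream derives from ``seed``; two runs with the
    same config produce byte-identical reports.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: list[str] = field(default_factory=lambda: ["ds.1.1", "m.1.1"])
    fit: FitConfig = field(default_factory=FitConfig)
    cv_axis: str = "subjects"
    cv_test_size: int | None = None
    horizon: int = 50
    consensus: str = "median"
    alpha: float = 0.01
    outdir: str = "reachlearn_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if isinstance(self.fit, dict):
            self.fit = FitConfig(**self.fit)
        # one seed to rule every stage
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.fit = dataclasses.replace(self.fit, seed=self.seed)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def write_trial_table(dataset: SyntheticDataset, outdir) -> tuple[Path, Path]:
    """Write the canonical trial CSV, the e0 sidecar and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials_path = outdir / "trials.csv"
    e0_path = outdir / "e0.csv"
    dataset.trials_frame().to_csv(trials_path, index=False)
    dataset.e0_frame().to_csv(e0_path, index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(dataset.manifest(), fh, indent=2, sort_keys=True)
    return trials_path, e0_path


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s) {missing}")


def read_trial_table(trials_path, e0_path) -> list[SubjectTaskSlice]:
    """Read and validate a trial table plus its e0 sidecar.

    Columns are matched by name, so header order is free.  Directions must
    lie in 1..6, vision must be boolean-coded, and a NaN observation on a
    vision trial is rejected with its row index.
    """
    trials = pd.read_csv(trials_path)
    e0s = pd.read_csv(e0_path)
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    _require_columns(e0s, ["subject", "task", "direction", "e0_cm"], "e0 sidecar")

    bad_dir = ~trials["direction"].isin(range(1, 7))
    if bad_dir.any():
        row = int(np.flatnonzero(bad_dir.to_numpy())[0])
        raise SchemaError(
            f"trial table row {row}: direction {trials['direction'].iloc[row]} "
            "outside 1..6"
        )
    if not trials["vision"].isin([0, 1, True, False]).all():
        raise SchemaError("vision column must be boolean (0/1)")
    nan_vision = trials["max_error_cm"].isna() & trials["vision"].astype(bool)
    if nan_vision.any():
        row = int(np.flatnonzero(nan_vision.to_numpy())[0])
        raise SchemaError(f"trial table row {row}: NaN observation on a vision trial")

    slices = []
    for (s, t), grp in trials.groupby(["subject", "task"], sort=True):
        grp = grp.sort_values("trial")
        e0_grp = e0s[(e0s.subject == s) & (e0s.task == t)].sort_values("direction")
        if len(e0_grp) != 6:
            raise SchemaError(f"subject {s} task {t}: need 6 e0 rows, found {len(e0_grp)}")
        schedule = TrialSchedule(
            direction=grp["direction"].to_numpy(),
            vision=grp["vision"].to_numpy().astype(bool),
            ea_gain=grp["ea_gain"].to_numpy(float),
            ea_offset=grp["ea_offset"].to_numpy(float),
        )
        slices.append(SubjectTaskSlice(
            subject=int(s), task=int(t), schedule=schedule,
            observed=grp["max_error_cm"].to_numpy(float),
            e0=e0_grp["e0_cm"].to_numpy(float),
        ))
    return slices


def _write_fits(fits_by_model, path) -> None:
    payload = {
        mid: [fr.to_dict() for _, fr in sorted(fits.items())]
        for mid, fits in fits_by_model.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_full_analysis(config: RunConfig) -> CVReport:
    """Run generation, fitting, selection and inference; write artifacts.

    Artifacts land in ``config.outdir``: trials.csv, e0.csv, manifest.json,
    fits.json, report.json, inference.csv and run.log.  Idempotent for a
    fixed config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        t0 = time.time()
        config.to_yaml(outdir / "config.yaml")
        log.info("stage=generate seed=%d", config.seed)
        dataset = generate_cohort(config.cohort)
        write_trial_table(dataset, outdir)

        kept, n_kept = exclude_gain_zero(dataset.slices)
        log.info("stage=exclude_gain_zero kept=%d of %d", n_kept, len(dataset.slices))

        log.info("stage=fit models=%s starts=%d", config.models, config.fit.n_starts)
        fits = fit_all(config.models, kept, config.fit)
        _write_fits(fits, outdir / "fits.json")

        log.info("stage=select axis=%s horizon=%d", config.cv_axis, config.horizon)
        report = cross_validate(
            fits, kept, axis=config.cv_axis, test_size=config.cv_test_size,
            horizon=config.horizon, alpha=config.alpha,
            consensus=config.consensus, momentum_mode=config.fit.momentum_mode,
        )
        report.to_json(outdir / "report.json")

        best = report.best_model
        best_fits = list(fits[best].values())
        if len(best_fits) >= 6:
            inference = parameter_inference(best_fits)
            inference.to_csv(outdir / "inference.csv", index=False)
            log.info("stage=infer model=%s rows=%d", best, len(inference))
        log.info("done elapsed=%.1fs best=%s", time.time() - t0, best)
        return report
    except Exception:
        log.exception("pipeline stage failed; partial outputs preserved in %s", outdir)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
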