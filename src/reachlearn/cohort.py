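"""Synthetic cohorts with the statistical structure of the randomized
reaching experiment.

A cohort is a set of subjects, each practicing eight visuomotor distortion
tasks for 250 trials.  Movement directions (six, the ordered vertex pairs of
the target triangle) are randomized and near-balanced within a task; one in
four trials withholds cursor feedback (no-vision), never twice in a row.
Error-augmentation feedback is assigned per subject x task: five subjects
receive normal feedback EA{gain 1, offset 0} throughout, the rest draw task
coordinates without replacement from the eleven non-normal EA coordinates,
with the same random order repeated for every pair of subjects.

Observed signed max-errors are the ground-truth model's latent practiced
error plus i.i.d. Gaussian observation noise.  Everything is reproducible
from a single integer seed, fanned out to per-subject/task generators
through ``numpy`` seed sequences keyed by (subject, task).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .kinematics import EACondition, EA_NORMAL, enumerate_ea_coordinates
from .models import (
    ModelParams,
    ModelSpec,
    TrialSchedule,
    simulate_learning_curves,
)

__all__ = [
    "CohortConfig",
    "SubjectTaskSlice",
    "SyntheticDataset",
    "default_ground_truth",
    "generate_schedule",
    "generate_cohort",
]

#: Latent magnitude beyond which a simulated cohort is flagged divergent.
_DIVERGENCE_CM = 1e6


def default_ground_truth() -> ModelParams:
    """Default generating model: first-order affine mixed model (m.1.1).

    Signs follow the fitted structure reported for this model family:
    positive offset ``A``, small positive direction-specific rate ``B``
    (forgetting between repetitions), negative generalization gain ``Z``
    with ``Z + B < 0`` at the practiced direction (net learning), and
    generalization weights that fall off steeply beyond a 60-degree
    separation (local generalization).  Magnitudes are chosen so the coupled
    dynamics stay bounded under randomized schedules with sign-alternating
    initial errors, decaying from ~20 cm toward a nonzero steady state.
    """
    spec = ModelSpec.from_id("m.1.1")
    return ModelParams(
        spec=spec,
        a=np.full(6, 0.5),
        b=np.full(6, 0.02),
        z=np.full(6, -0.40),
        # W at separations (-120, -60, 60, 120, 180)
        w=np.array([0.06, 0.15, 0.15, 0.06, 0.03]),
    )


@dataclass
class CohortConfig:
    """Study-design knobs for a synthetic cohort.

    Defaults mirror the experiment: 15 subjects x 8 tasks x 250 trials over
    6 directions, a quarter of trials without vision, initial-exposure error
    magnitudes around 20.19 cm.  ``noise_sd`` is the standard deviation of
    the additive Gaussian observation noise on the signed max-error (cm);
    ``noise_df`` switches to Student-t noise with that many degrees of
    freedom for robustness experiments.  ``truth_jitter_rel`` perturbs each
    subject's generating parameters by a relative Gaussian factor (0
    disables inter-subject variability).
    """

    n_subjects: int = 15
    n_tasks: int = 8
    trials_per_task: int = 250
    n_directions: int = 6
    novision_fraction: float = 0.25
    ea_scheme: str = "randomized_paper"   # or "all_normal"
    n_normal_subjects: int = 5
    noise_sd: float = 2.0
    noise_df: float | None = None
    e0_mean_cm: float = 20.19
    e0_spread_cm: float = 3.0
    truth_jitter_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.novision_fraction <= 0.5:
            raise ValueError(
                "no-vision fraction above 1/2 cannot avoid adjacent no-vision trials"
            )
        if self.ea_scheme not in ("randomized_paper", "all_normal"):
            raise ValueError(f"unknown EA scheme {self.ea_scheme!r}")


@dataclass
class SubjectTaskSlice:
    """One subject x task learning phase: schedule, e0 and observations.

    This is the unit the fitting stage consumes, whether generated here or
    read back from disk.  ``observed`` holds the per-trial signed max-error
    (cm) at that trial's practiced direction; ``e0`` the per-direction
    initial-exposure errors.
    """

    subject: int
    task: int
    schedule: TrialSchedule
    observed: np.ndarray
    e0: np.ndarray
    ea: EACondition | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.e0 = np.asarray(self.e0, dtype=float)
        if len(self.observed) != len(self.schedule):
            raise ValueError("one observation per scheduled trial required")

    @property
    def key(self) -> tuple[int, int]:
        return (self.subject, self.task)


@dataclass
class SyntheticDataset:
    """A generated cohort plus its ground truth and provenance."""

    config: CohortConfig
    slices: list[SubjectTaskSlice]
    ground_truth: ModelParams | None = None
    subject_truths: dict[int, ModelParams] = field(default_factory=dict)
    diverged: bool = False

    def trials_frame(self) -> pd.DataFrame:
        """Canonical long-format trial table (trial index 1-based)."""
        rows = []
        for sl in self.slices:
            n = len(sl.schedule)
            rows.append(pd.DataFrame({
                "subject": sl.subject,
                "task": sl.task,
                "trial": np.arange(1, n + 1),
                "direction": sl.schedule.direction,
                "vision": sl.schedule.vision.astype(int),
                "ea_gain": sl.schedule.ea_gain,
                "ea_offset": sl.schedule.ea_offset,
                "max_error_cm": sl.observed,
            }))
        return pd.concat(rows, ignore_index=True)

    def e0_frame(self) -> pd.DataFrame:
        rows = []
        for sl in self.slices:
            for d in range(len(sl.e0)):
                rows.append((sl.subject, sl.task, d + 1, sl.e0[d]))
        return pd.DataFrame(rows, columns=["subject", "task", "direction", "e0_cm"])

    def manifest(self) -> dict:
        out = {"config": asdict(self.config), "diverged": self.diverged}
        if self.ground_truth is not None:
            out["ground_truth"] = self.ground_truth.to_dict()
        if self.subject_truths:
            out["subject_truths"] = {
                str(s): p.to_dict() for s, p in self.subject_truths.items()
            }
        return out

    def get_slice(self, subject: int, task: int) -> SubjectTaskSlice:
        for sl in self.slices:
            if sl.key == (subject, task):
                return sl
        raise KeyError((subject, task))

    @property
    def subjects(self) -> list[int]:
        return sorted({sl.subject for sl in self.slices})

    @property
    def tasks(self) -> list[int]:
        return sorted({sl.task for sl in self.slices})


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-style child generator: global seed plus an integer key path."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_schedule(
    n_trials: int,
    n_directions: int = 6,
    novision_fraction: float = 0.25,
    ea: EACondition = EA_NORMAL,
    rng: np.random.Generator | None = None,
) -> TrialSchedule:
    """Randomized direction sequence with near-balanced counts and
    non-adjacent no-vision trials.

    Per-direction counts differ by at most one; the number of no-vision
    trials is ``floor(n_trials * fraction)`` placed uniformly at random
    among the non-adjacent position sets.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= novision_fraction <= 0.5:
        raise ValueError("no-vision fraction must be in [0, 1/2] for non-adjacency")
    base, rem = divmod(n_trials, n_directions)
    counts = np.full(n_directions, base)
    counts[rng.choice(n_directions, size=rem, replace=False)] += 1
    direction = np.repeat(np.arange(1, n_directions + 1), counts)
    rng.shuffle(direction)

    n_nv = int(np.floor(n_trials * novision_fraction))
    vision = np.ones(n_trials, dtype=bool)
    if n_nv > 0:
        # uniform sample of a non-adjacent index set via the gap construction
        slots = rng.choice(n_trials - n_nv + 1, size=n_nv, replace=False)
        slots.sort()
        vision[slots + np.arange(n_nv)] = False
    return TrialSchedule.constant_ea(direction, vision, ea)


def _assign_ea(config: CohortConfig, subject: int) -> list[EACondition]:
    """Per-task EA coordinates for one subject (0-based subject index)."""
    if config.ea_scheme == "all_normal" or subject < config.n_normal_subjects:
        return [EA_NORMAL] * config.n_tasks
    pool = [c for c in enumerate_ea_coordinates() if not c.is_normal]
    pair = (subject - config.n_normal_subjects) // 2
    rng = _child_rng(config.seed, 1, pair)   # shared within a subject pair
    order = rng.permutation(len(pool))[: config.n_tasks]
    if config.n_tasks > len(pool):
        raise ValueError("more tasks than non-normal EA coordinates")
    return [pool[i] for i in order]


def _draw_e0(config: CohortConfig, task: int, rng: np.random.Generator) -> np.ndarray:
    """Initial-exposure errors: |N(mean, spread^2)| magnitudes with a
    direction sign pattern that alternates and flips with task parity."""
    mags = np.abs(rng.normal(config.e0_mean_cm, config.e0_spread_cm,
                             config.n_directions))
    signs = np.array([(-1) ** (d + task) for d in range(config.n_directions)])
    return mags * signs


def generate_cohort(
    config: CohortConfig,
    ground_truth: ModelParams | None = None,
) -> SyntheticDataset:
    """Simulate a full cohort from a generating model.

    Latent learning curves come from :func:`simulate_learning_curves` seeded
    at the drawn initial-exposure errors; the observation at each trial is
    the latent error of the practiced direction plus noise.  Two calls with
    the same config produce identical datasets.
    """
    truth = ground_truth if ground_truth is not None else default_ground_truth()
    spec = truth.spec
    slices: list[SubjectTaskSlice] = []
    subject_truths: dict[int, ModelParams] = {}
    diverged = False
    for s in range(config.n_subjects):
        subj_truth = truth
        if config.truth_jitter_rel > 0:
            jrng = _child_rng(config.seed, 2, s)
            vec = truth.to_vector()
            vec = vec * (1.0 + config.truth_jitter_rel * jrng.standard_normal(len(vec)))
            if spec.has_w:
                vec[-len(truth.w):] = np.clip(vec[-len(truth.w):], -1.0, 1.0)
            subj_truth = ModelParams.from_vector(spec, vec)
        subject_truths[s + 1] = subj_truth
        ea_by_task = _assign_ea(config, s)
        for t in range(config.n_tasks):
            rng = _child_rng(config.seed, 0, s, t)
            schedule = generate_schedule(
                config.trials_per_task, config.n_directions,
                config.novision_fraction, ea_by_task[t], rng,
            )
            e0 = _draw_e0(config, t, rng)
            curves = simulate_learning_curves(spec, subj_truth, e0, schedule)
            latent = curves.practiced_curve
            if np.any(~np.isfinite(latent)) or np.max(np.abs(latent)) > _DIVERGENCE_CM:
                diverged = True
            if config.noise_sd > 0:
                if config.noise_df is not None:
                    noise = config.noise_sd * rng.standard_t(config.noise_df, len(latent))
                else:
                    noise = rng.normal(0.0, config.noise_sd, len(latent))
            else:
                noise = np.zeros(len(latent))
            slices.append(SubjectTaskSlice(
                subject=s + 1, task=t + 1, schedule=schedule,
                observed=latent + noise, e0=e0, ea=ea_by_task[t],
            ))
    if diverged:
        warnings.warn("ground-truth dynamics diverged for at least one slice")
    return SyntheticDataset(
        config=config, slices=slices, ground_truth=truth,
        subject_truths=subject_truths, diverged=diverged,
    )
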