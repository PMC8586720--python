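"""Exhaustive cross-validation model selection and parameter inference.

Candidate structures are compared by how well a consensus model built from
training-set fits predicts held-out learning curves.  Partitions are
exhaustive: every C(n, k) split of subjects (or of tasks within a subject)
is evaluated.  Test accuracy per partition is summarised as the mode (KDE
maximum-likelihood estimate) of the per-curve RMSEs over the first 50
trials, where the decaying learning transient still dominates the noise
floor.  Models are then compared pairwise with left-tailed Wilcoxon
signed-rank tests (Bonferroni-corrected) and ranked by the resulting score
(wins minus losses).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, gaussian_kde, kruskal, wilcoxon

from .cohort import SubjectTaskSlice
from .fitting import FitResult, predict_observations
from .models import ModelParams, ModelSpec, W_SEPARATIONS_DEG, count_free_parameters

__all__ = [
    "Partition",
    "CVReport",
    "enumerate_partitions",
    "consensus_model",
    "test_rmse",
    "rmse_mle",
    "compare_models",
    "model_scores",
    "cross_validate",
    "parameter_inference",
]

#: Default test-set sizes: 3 of 15 subjects, 2 of 8 tasks (the 1/5 splits
#: that produce 455 and 28 exhaustive partitions).
DEFAULT_TEST_SIZE = {"subjects": 3, "tasks_within_subject": 2}


@dataclass(frozen=True)
class Partition:
    """One exhaustive train/test split along one CV axis."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    axis: str = "subjects"
    subject: int | None = None   # set for within-subject task partitions


def enumerate_partitions(
    n_items: int, test_size: int, axis: str = "subjects",
    items: Sequence[int] | None = None,
) -> list[Partition]:
    """All C(n_items, test_size) train/test splits in deterministic order."""
    if not 0 < test_size < n_items:
        raise ValueError("test_size must be strictly between 0 and n_items")
    ids = tuple(items) if items is not None else tuple(range(1, n_items + 1))
    out = []
    for test in itertools.combinations(ids, test_size):
        train = tuple(i for i in ids if i not in test)
        out.append(Partition(train=train, test=test, axis=axis))
    return out


def consensus_model(
    fits: Sequence[FitResult], method: str = "median"
) -> ModelParams:
    """Element-wise median (or mean) of parameters across training fits."""
    if not fits:
        raise ValueError("need at least one fit")
    spec = fits[0].spec
    if any(f.spec.model_id != spec.model_id for f in fits):
        raise ValueError("fits mix different model structures")
    mat = np.vstack([f.params.to_vector() for f in fits])
    if method == "median":
        vec = np.median(mat, axis=0)
    elif method == "average":
        vec = np.mean(mat, axis=0)
    else:
        raise ValueError(f"unknown consensus method {method!r}")
    return ModelParams.from_vector(spec, vec)


def test_rmse(
    consensus: ModelParams,
    data: SubjectTaskSlice,
    horizon: int = 50,
    momentum_mode: str = "normal_feedback",
) -> float:
    """Prediction RMSE of a consensus model over the first ``horizon``
    trials of a held-out slice, simulated from the slice's own e0/schedule."""
    n = min(horizon, len(data.observed))
    if n == 0:
        raise ValueError("no observations within the evaluation horizon")
    pred = predict_observations(consensus.spec, consensus, data, momentum_mode)
    resid = pred[:n] - data.observed[:n]
    return float(np.sqrt(np.mean(resid**2)))


def rmse_mle(values: Sequence[float]) -> float:
    """Mode of a Gaussian KDE over an RMSE sample.

    Silverman bandwidth; the mode is located on a 512-point grid spanning
    the sample range padded by three bandwidths.  Degenerate samples (single
    value, or zero spread) return the value itself.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or len(vals) == 0:
        raise ValueError("need a non-empty 1-d sample")
    if len(vals) == 1 or np.ptp(vals) == 0:
        return float(vals[0])
    kde = gaussian_kde(vals, bw_method="silverman")
    bw = float(kde.factor * vals.std(ddof=1))
    grid = np.linspace(vals.min() - 3 * bw, vals.max() + 3 * bw, 512)
    return float(grid[np.argmax(kde(grid))])


def compare_models(
    mle_a: Sequence[float], mle_b: Sequence[float], n_comparisons: int = 1
) -> float:
    """Left-tailed Wilcoxon signed-rank p-value that model A's partition
    MLEs are lower than model B's, multiplied by the Bonferroni factor
    (clipped at 1).  All-zero differences return 1 by convention."""
    a = np.asarray(mle_a, dtype=float)
    b = np.asarray(mle_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        return 1.0
    p = float(wilcoxon(a, b, alternative="less").pvalue)
    return min(1.0, p * n_comparisons)


def model_scores(significant: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Score per model: row wins minus column losses of a boolean
    significance matrix (entry [i, j] true iff model i beat model j)."""
    mat = np.asarray(significant, dtype=bool)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("significance matrix must be square")
    return mat.sum(axis=1).astype(int) - mat.sum(axis=0).astype(int)


@dataclass
class CVReport:
    """Cross-validation outcome for a set of candidate models.

    ``mle`` is partitions x models; ``pvalues``/``significant`` are the
    ordered pairwise Wilcoxon matrices; ``ranking`` orders models by score,
    breaking ties by mean partition MLE and then by parameter count (the
    score is integer-valued and saturates at small partition counts, so a
    predictive-accuracy tie-break is needed to name a single winner).
    """

    models: list[str]
    axis: str
    alpha: float
    horizon: int
    consensus: str
    partitions: list[Partition]
    mle: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    scores: np.ndarray
    ranking: list[str]

    @property
    def best_model(self) -> str:
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "axis": self.axis,
            "alpha": self.alpha,
            "horizon": self.horizon,
            "consensus": self.consensus,
            "n_partitions": len(self.partitions),
            "mle": self.mle.tolist(),
            "pvalues": self.pvalues.tolist(),
            "significant": self.significant.astype(int).tolist(),
            "scores": self.scores.tolist(),
            "ranking": self.ranking,
            "best_model": self.best_model,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _partition_mle(
    spec: ModelSpec,
    fits: Mapping[tuple[int, int], FitResult],
    slices: Mapping[tuple[int, int], SubjectTaskSlice],
    train_keys: Sequence[tuple[int, int]],
    test_keys: Sequence[tuple[int, int]],
    horizon: int,
    consensus: str,
    momentum_mode: str,
) -> float:
    cons = consensus_model([fits[k] for k in train_keys], method=consensus)
    rmses = [test_rmse(cons, slices[k], horizon, momentum_mode) for k in test_keys]
    return rmse_mle(rmses)


def cross_validate(
    fits_by_model: Mapping[str, Mapping[tuple[int, int], FitResult]],
    slices: Sequence[SubjectTaskSlice],
    axis: str = "subjects",
    test_size: int | None = None,
    horizon: int = 50,
    alpha: float = 0.01,
    consensus: str = "median",
    momentum_mode: str = "normal_feedback",
) -> CVReport:
    """Exhaustive CV over subjects or over tasks within subject.

    For each partition and model, a consensus (median by default) of the
    training-set fits predicts each held-out subject x task curve over the
    first ``horizon`` trials; the partition is summarised by the KDE mode of
    those RMSEs.  Pairwise left-tailed Wilcoxon tests across partitions,
    Bonferroni-corrected by the number of ordered pairs, yield the
    significance matrix and scores.
    """
    models = list(fits_by_model)
    by_key = {sl.key: sl for sl in slices}
    subjects = sorted({k[0] for k in by_key})
    tasks = sorted({k[1] for k in by_key})
    if axis == "subjects":
        tsize = test_size if test_size is not None else DEFAULT_TEST_SIZE[axis]
        parts = enumerate_partitions(len(subjects), tsize, axis, items=subjects)
        split_keys = [
            (
                [k for k in by_key if k[0] in p.train],
                [k for k in by_key if k[0] in p.test],
            )
            for p in parts
        ]
    elif axis == "tasks_within_subject":
        tsize = test_size if test_size is not None else DEFAULT_TEST_SIZE[axis]
        parts = []
        split_keys = []
        for s in subjects:
            for p in enumerate_partitions(len(tasks), tsize, axis, items=tasks):
                parts.append(Partition(p.train, p.test, axis, subject=s))
                split_keys.append(
                    ([(s, t) for t in p.train], [(s, t) for t in p.test])
                )
    else:
        raise ValueError(f"unknown CV axis {axis!r}")

    mle = np.empty((len(parts), len(models)))
    for j, mid in enumerate(models):
        spec = ModelSpec.from_id(mid)
        fits = fits_by_model[mid]
        for i, (train_keys, test_keys) in enumerate(split_keys):
            mle[i, j] = _partition_mle(
                spec, fits, by_key, train_keys, test_keys,
                horizon, consensus, momentum_mode,
            )

    m = len(models)
    factor = m * (m - 1)
    pvals = np.ones((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                pvals[i, j] = compare_models(mle[:, i], mle[:, j], factor)
    sig = pvals < alpha
    np.fill_diagonal(sig, False)
    scores = model_scores(sig)

    order = sorted(
        range(m),
        key=lambda i: (
            -scores[i],
            mle[:, i].mean(),
            count_free_parameters(ModelSpec.from_id(models[i])),
            models[i],
        ),
    )
    return CVReport(
        models=models, axis=axis, alpha=alpha, horizon=horizon,
        consensus=consensus, partitions=parts, mle=mle, pvalues=pvals,
        significant=sig, scores=scores, ranking=[models[i] for i in order],
    )


def parameter_inference(
    fits: Sequence[FitResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Parameter-level statistics across subject x task fits of one model.

    Per flat parameter: the median value, a sign-test p-value for a non-zero
    median, and Kruskal-Wallis p-values with learning task and (for
    per-direction parameters) movement direction as factors.  For mixed
    models the effective learning rates are appended: ``B+Z`` per direction
    (the net rate when the direction is practiced) and ``Z*W(theta)`` per
    separation (the generalized rate).
    """
    if len(fits) < 6:
        raise ValueError("need at least 6 fits for parameter inference")
    spec = fits[0].spec
    if any(f.spec.model_id != spec.model_id for f in fits):
        raise ValueError("fits mix different model structures")
    names = fits[0].params.parameter_names()
    mat = np.vstack([f.params.to_vector() for f in fits])
    tasks = np.array([f.task if f.task is not None else -1 for f in fits])

    records = []

    def sign_test_p(x: np.ndarray) -> float:
        nz = x[x != 0]
        if len(nz) == 0:
            return 1.0
        return float(binomtest(int((nz > 0).sum()), len(nz), 0.5).pvalue)

    def kw_p(values: np.ndarray, groups: np.ndarray) -> float:
        samples = [values[groups == g] for g in np.unique(groups)]
        samples = [s for s in samples if len(s) > 0]
        if len(samples) < 2:
            return np.nan
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(values) == 0:
            return 1.0
        return float(kruskal(*samples).pvalue)

    # group columns by base parameter (A, B1, ..., Z, W(theta))
    base_of = [n.split("[")[0] if "[" in n else n for n in names]
    direction_of = [
        int(n.split("[")[1].rstrip("]")) if "[" in n else None for n in names
    ]
    for base in dict.fromkeys(base_of):
        cols = [i for i, b in enumerate(base_of) if b == base]
        vals = mat[:, cols].ravel()
        task_groups = np.repeat(tasks, len(cols))
        if direction_of[cols[0]] is not None:
            dir_groups = np.tile([direction_of[i] for i in cols], len(fits))
            kw_dir = kw_p(vals, dir_groups)
        else:
            kw_dir = np.nan
        records.append({
            "parameter": base,
            "median": float(np.median(vals)),
            "sign_test_p": sign_test_p(vals),
            "kw_task_p": kw_p(vals, task_groups),
            "kw_direction_p": kw_dir,
            "significant_nonzero": sign_test_p(vals) < alpha,
        })

    if spec.has_z and spec.has_w and spec.order == 1:
        iz = [i for i, b in enumerate(base_of) if b == "Z"]
        ib = [i for i, b in enumerate(base_of) if b == "B1"]
        eff = (mat[:, ib] + mat[:, iz]).ravel()
        records.append({
            "parameter": "B+Z (theta=0)",
            "median": float(np.median(eff)),
            "sign_test_p": sign_test_p(eff),
            "kw_task_p": kw_p(eff, np.repeat(tasks, len(ib))),
            "kw_direction_p": np.nan,
            "significant_nonzero": sign_test_p(eff) < alpha,
        })
        for si, sep in enumerate(W_SEPARATIONS_DEG):
            iw = names.index(f"W({sep})")
            zw = (mat[:, iz] * mat[:, [iw]]).ravel()
            records.append({
                "parameter": f"Z*W({sep})",
                "median": float(np.median(zw)),
                "sign_test_p": sign_test_p(zw),
                "kw_task_p": kw_p(zw, np.repeat(tasks, len(iz))),
                "kw_direction_p": np.nan,
                "significant_nonzero": sign_test_p(zw) < alpha,
            })
    return pd.DataFrame.from_records(records)


def plot_model_scores(report: CVReport, path=None):
    """Bar chart of model scores (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(report.models, report.scores)
    ax.set_ylabel("model score (wins - losses)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
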