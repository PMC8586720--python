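"""Simulation-based nonlinear least squares.

There is no closed-form regression from one trial's observation to the
next: directions repeat sparsely and every direction's latent state evolves
every trial.  Parameters are therefore estimated by forward-simulating the
full learning curve from the initial-exposure errors and minimising the sum
of squared differences between the simulated and observed errors at the
practiced-direction trials (vision and no-vision alike), jointly across all
six directions of a subject x task phase.  A multi-start bounded
trust-region search (Latin-hypercube initial points) stands in for the
global search; the contract is "best of ``n_starts`` within bounds", not a
particular global optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .cohort import SubjectTaskSlice, SyntheticDataset
from .models import (
    ModelParams,
    ModelSpec,
    W_SEPARATIONS_DEG,
    count_free_parameters,
    simulate_learning_curves,
)
from .models import _NL_CODE, _SCHEME_CODE, _simulate_kernel, _w_lookup

__all__ = [
    "FitConfig",
    "FitResult",
    "DEFAULT_BOUNDS",
    "parameter_bounds",
    "predict_observations",
    "loss",
    "fit",
    "fit_all",
    "exclude_gain_zero",
]

#: Box constraints by parameter class.  Only the W bounds are part of the
#: model definition; the rest are generous search boxes.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (-10.0, 10.0),   # cm per trial
    "b": (-2.0, 2.0),
    "c": (-1.0, 1.0),     # 1/cm
    "d": (-0.1, 0.1),     # 1/cm^2
    "h": (0.1, 100.0),    # cm
    "z": (-2.0, 2.0),
    "w": (-1.0, 1.0),
}


@dataclass
class FitConfig:
    """Multi-start optimizer settings.

    ``n_starts`` defaults to a desk-scale 50 (the full-scale analysis used a
    1000-fold global search); fits are deterministic given (seed, n_starts).
    """

    n_starts: int = 50
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int | None = None
    momentum_mode: str = "normal_feedback"
    # global-search staging: local solves start from the most promising
    # fraction of the trial points, capped during exploration, and the best
    # solution is polished at full tolerance
    local_fraction: float = 0.3
    explore_nfev: int = 60

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        # normalise bound pairs so configs round-trip through YAML/JSON
        self.bounds = {k: (float(v[0]), float(v[1])) for k, v in self.bounds.items()}


@dataclass
class FitResult:
    """Estimated parameters and goodness of fit for one subject x task."""

    spec: ModelSpec
    params: ModelParams
    sse: float
    r2: float
    r2_adj: float
    n_obs: int
    converged: bool
    start_count: int
    subject: int | None = None
    task: int | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.spec.model_id,
            "subject": self.subject,
            "task": self.task,
            "params": self.params.to_dict(),
            "sse": self.sse,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "start_count": self.start_count,
        }


def parameter_bounds(
    spec: ModelSpec, bounds: Mapping[str, tuple[float, float]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper bound vectors in the flat parameter layout."""
    bx = dict(DEFAULT_BOUNDS)
    if bounds:
        bx.update(bounds)
    nd = spec.n_directions
    lo: list[np.ndarray] = []
    hi: list[np.ndarray] = []

    def add(name: str, n: int) -> None:
        lo.append(np.full(n, bx[name][0]))
        hi.append(np.full(n, bx[name][1]))

    if spec.has_a:
        add("a", nd)
    for _ in range(spec.order):
        add("b", nd)
    if spec.has_c:
        add("c", nd)
    if spec.has_d:
        add("d", nd)
    if spec.has_h:
        add("h", nd)
    if spec.has_z:
        add("z", nd)
    if spec.has_w:
        add("w", len(W_SEPARATIONS_DEG))
    return np.concatenate(lo), np.concatenate(hi)


def predict_observations(
    spec: ModelSpec,
    params: ModelParams,
    data: SubjectTaskSlice,
    momentum_mode: str = "normal_feedback",
) -> np.ndarray:
    """Model prediction of the observed error at each trial's practiced
    direction, simulated from the slice's own e0 and schedule."""
    curves = simulate_learning_curves(
        spec, params, data.e0, data.schedule, momentum_mode=momentum_mode)
    return curves.practiced_curve


def loss(
    spec: ModelSpec,
    params: ModelParams,
    data: SubjectTaskSlice,
    momentum_mode: str = "normal_feedback",
) -> float:
    """Sum of squared simulated-minus-observed errors over all trials."""
    if data.e0 is None or len(data.e0) != spec.n_directions:
        raise ValueError("slice is missing per-direction initial-exposure errors")
    resid = predict_observations(spec, params, data, momentum_mode) - data.observed
    return float(np.dot(resid, resid))


def _fast_predictor(spec: ModelSpec, data: SubjectTaskSlice, momentum_mode: str):
    """Closure mapping a flat parameter vector straight to the predicted
    observations via the simulation kernel.

    Skips :class:`ModelParams` construction/validation — the optimizer calls
    this tens of thousands of times.  Agreement with the documented
    :func:`predict_observations` path is covered by tests.
    """
    nd, k = spec.n_directions, spec.order
    scheme = _SCHEME_CODE[spec.scheme]
    nl = _NL_CODE[spec.nonlinearity]
    momentum = 1 if momentum_mode == "repeat_delta" else 0
    e0 = np.ascontiguousarray(data.e0, dtype=float)
    practiced0 = data.schedule.direction - 1
    vision = data.schedule.vision
    gain = data.schedule.ea_gain
    offset = data.schedule.ea_offset
    rows = np.arange(len(practiced0))
    ones = np.ones(nd)
    zeros = np.zeros(nd)
    nw = len(W_SEPARATIONS_DEG)

    def predict(x: np.ndarray) -> np.ndarray:
        pos = 0

        def take(n):
            nonlocal pos
            out = x[pos:pos + n]
            pos += n
            return out

        a = take(nd) if spec.has_a else zeros
        b = np.ascontiguousarray(np.column_stack([take(nd) for _ in range(k)]))
        c = take(nd) if spec.has_c else zeros
        d = take(nd) if spec.has_d else zeros
        h = take(nd) if spec.has_h else ones
        z = take(nd) if spec.has_z else zeros
        w6 = _w_lookup(take(nw)) if spec.has_w else _w_lookup(np.zeros(nw))
        latent = _simulate_kernel(scheme, k, nl, momentum, a, b, c, d, h, z, w6,
                                  e0, practiced0, vision, gain, offset)
        return latent[rows, practiced0]

    return predict


def _start_points(
    spec: ModelSpec, lo: np.ndarray, hi: np.ndarray, n_starts: int, seed: int
) -> np.ndarray:
    """Latin-hypercube starts over the bound box, plus one neutral start at
    the box centre with zeroed rate terms (a plausible no-learning model)."""
    n_par = len(lo)
    neutral = (lo + hi) / 2.0
    if n_starts == 1:
        return neutral[None, :]
    sampler = qmc.LatinHypercube(d=n_par, seed=seed)
    pts = qmc.scale(sampler.random(n_starts - 1), lo, hi)
    return np.vstack([neutral[None, :], pts])


def fit(
    spec: ModelSpec,
    data: SubjectTaskSlice,
    config: FitConfig | None = None,
) -> FitResult:
    """Best-of-``n_starts`` bounded least-squares fit of one slice.

    R^2 is computed about the observed mean; adjusted R^2 penalises by the
    structure's free-parameter count.  If every start fails the result is
    returned flagged ``converged=False`` with the least-bad parameters.
    """
    if config is None:
        config = FitConfig()
    lo, hi = parameter_bounds(spec, config.bounds)
    obs = data.observed
    n = len(obs)
    p = count_free_parameters(spec)

    predictor = _fast_predictor(spec, data, config.momentum_mode)

    def residuals(x: np.ndarray) -> np.ndarray:
        r = predictor(x) - obs
        # keep the optimizer on the rails if a start diverges
        return np.clip(np.nan_to_num(r, nan=1e8), -1e8, 1e8)

    starts = _start_points(spec, lo, hi, config.n_starts, config.seed)
    # stage 1: rank trial points by raw sse, run capped local solves from
    # the most promising ones
    sse0 = np.array([float(np.sum(residuals(x) ** 2)) for x in starts])
    n_local = max(3, int(np.ceil(config.local_fraction * len(starts))))
    n_local = min(n_local, len(starts))
    best_x, best_sse, any_ok = None, np.inf, False
    for idx in np.argsort(sse0)[:n_local]:
        try:
            res = least_squares(
                residuals, starts[idx], bounds=(lo, hi), method="trf",
                x_scale="jac", ftol=config.ftol, xtol=config.xtol,
                gtol=config.gtol, max_nfev=config.explore_nfev,
            )
        except Exception:
            continue
        sse = 2.0 * res.cost
        any_ok = any_ok or res.status > 0
        if sse < best_sse:
            best_sse, best_x = sse, res.x
    if best_x is None:
        best_x = starts[int(np.argmin(sse0))]
        best_sse = float(sse0.min())
        any_ok = False
    else:
        # stage 2: polish the winner at full tolerance
        try:
            res = least_squares(
                residuals, best_x, bounds=(lo, hi), method="trf",
                x_scale="jac", ftol=config.ftol, xtol=config.xtol,
                gtol=config.gtol, max_nfev=config.max_nfev,
            )
            if 2.0 * res.cost <= best_sse:
                best_sse, best_x = 2.0 * res.cost, res.x
        except Exception:
            pass
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - best_sse / sstot if sstot > 0 else (1.0 if best_sse == 0 else -np.inf)
    denom = n - p - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else np.nan
    return FitResult(
        spec=spec,
        params=ModelParams.from_vector(spec, best_x),
        sse=float(best_sse),
        r2=float(r2),
        r2_adj=float(r2_adj),
        n_obs=n,
        converged=bool(any_ok),
        start_count=len(starts),
        subject=data.subject,
        task=data.task,
    )


def exclude_gain_zero(
    slices: Iterable[SubjectTaskSlice],
) -> tuple[list[SubjectTaskSlice], int]:
    """Drop subject x task slices whose EA-gain is zero.

    With zero gain the perceived error never varies with performance, so the
    learning-rate terms are unidentifiable.  Returns the retained slices and
    their count; idempotent.
    """
    kept = [sl for sl in slices if not np.any(sl.schedule.ea_gain == 0)]
    return kept, len(kept)


def fit_all(
    model_ids: Sequence[str],
    slices: Sequence[SubjectTaskSlice],
    config: FitConfig | None = None,
) -> dict[str, dict[tuple[int, int], FitResult]]:
    """Fit every candidate model to every slice.

    Per-fit seeds are derived deterministically from the config seed and the
    (model, subject, task) key so results do not depend on iteration order.
    """
    if config is None:
        config = FitConfig()
    out: dict[str, dict[tuple[int, int], FitResult]] = {}
    for mi, mid in enumerate(model_ids):
        spec = ModelSpec.from_id(mid)
        fits: dict[tuple[int, int], FitResult] = {}
        for sl in slices:
            sub_seed = int(
                np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(mi, sl.subject, sl.task)
                ).generate_state(1)[0] % (2**31)
            )
            cfg = FitConfig(**{**asdict(config), "seed": sub_seed})
            fits[sl.key] = fit(spec, sl, cfg)
        out[mid] = fits
    return out
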