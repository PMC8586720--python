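"""The trial-to-trial learning model family.

Twenty-eight state-space model structures describe how the signed maximum
error of the initial reach launch is updated from one trial to the next by
the visually perceived error.  A model is identified by a string id
``"<scheme>.<order>.<nonlinearity>"``:

* scheme ``ds`` (direction-specific): each of the six movement directions
  keeps its own latent error ``e_d`` updated only from its own perceived
  error; ``g`` (generalizing): every direction is driven by the practiced
  direction's perceived error through an angular kernel ``W(theta)``;
  ``m`` (mixed): the direction-specific update plus a linear generalization
  term ``Z_d * W(theta) * e_hat_p``.
* order ``k``: the update uses the perceived error of the last ``k`` trials.
* nonlinearity: ``1L`` linear (no offset), ``1`` affine, ``2`` quadratic,
  ``3`` cubic, ``1G`` Gaussian-weighted learning rate.

The latent state update is

    e[n+1, d] = e[n, d] + f_d(e_hat[n, d])            (ds)
    e[n+1, d] = e[n, d] + f_d(g_hat[n, d])            (g)
    e[n+1, d] = e[n, d] + f_d(e_hat[n, d]) + Z_d * g_hat[n, d]   (m)

with the perceived error ``e_hat = gain * e + offset * e0`` under the
trial's error-augmentation condition (zero on no-vision trials), and the
generalized error ``g_hat[n, d] = W(theta_{d,p}) * e_hat[n, p]``.  Every
direction updates on every trial: unpracticed directions evolve under the
momentum rule, i.e. their perceived error is computed as if normal feedback
EA{gain 1, offset 0} applied to the latent state.  For generalizing-scheme
models the structure coefficients act on the generalized error and are
conventionally relabelled B, C, D -> Z, Y, X; the field names here stay
structural (a, b, c, d).

Units: all errors are display centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from numba import njit

from .kinematics import EACondition, EA_NORMAL

__all__ = [
    "ModelSpec",
    "ModelParams",
    "TrialSchedule",
    "TrialEntry",
    "LearningState",
    "LearningCurveSet",
    "MODEL_IDS",
    "N_DIRECTIONS",
    "W_SEPARATIONS_DEG",
    "separation_deg",
    "count_free_parameters",
    "perceived_error",
    "generalized_error",
    "delta_f",
    "initial_state",
    "step",
    "simulate_learning_curves",
]

N_DIRECTIONS = 6

#: Angular separations (deg) carrying a free generalization weight; W(0) = 1.
W_SEPARATIONS_DEG = (-120, -60, 60, 120, 180)

_SCHEMES = ("ds", "g", "m")
_NONLINEARITIES = ("1L", "1", "2", "3", "1G")

# Allowed (order, nonlinearity) combinations per scheme; together these
# enumerate exactly the 28 candidate structures.
_ALLOWED = {
    "ds": {(1, "1G"), (1, "3"), (1, "2"), (1, "1"), (1, "1L")}
    | {(k, "1") for k in range(2, 9)}
    | {(k, "2") for k in range(2, 5)},
    "g": {(1, "3"), (1, "2"), (1, "1"), (1, "1L"), (2, "1"), (3, "1")},
    "m": {(1, "3"), (1, "2"), (1, "1"), (1, "1L"), (2, "1"), (3, "1"), (4, "1")},
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the 28 model structures."""

    scheme: str
    order: int
    nonlinearity: str
    n_directions: int = N_DIRECTIONS

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if (self.order, self.nonlinearity) not in _ALLOWED[self.scheme]:
            raise ValueError(
                f"{self.scheme}.{self.order}.{self.nonlinearity} is not one of "
                "the 28 candidate structures"
            )

    @property
    def model_id(self) -> str:
        return f"{self.scheme}.{self.order}.{self.nonlinearity}"

    @classmethod
    def from_id(cls, model_id: str, n_directions: int = N_DIRECTIONS) -> "ModelSpec":
        scheme, order, nl = model_id.split(".")
        return cls(scheme=scheme, order=int(order), nonlinearity=nl,
                   n_directions=n_directions)

    # -- active parameter fields ------------------------------------------
    @property
    def has_a(self) -> bool:
        return self.nonlinearity != "1L"

    @property
    def has_c(self) -> bool:
        return self.nonlinearity in ("2", "3")

    @property
    def has_d(self) -> bool:
        return self.nonlinearity == "3"

    @property
    def has_h(self) -> bool:
        return self.nonlinearity == "1G"

    @property
    def has_z(self) -> bool:
        return self.scheme == "m"

    @property
    def has_w(self) -> bool:
        return self.scheme in ("g", "m")


#: The 28 candidate model ids in the published order.
MODEL_IDS = (
    ["ds.1.1G", "ds.1.3", "ds.1.2", "ds.1.1", "ds.1.1L"]
    + [f"ds.{k}.1" for k in range(2, 9)]
    + ["ds.2.2", "ds.3.2", "ds.4.2"]
    + ["g.1.3", "g.1.2", "g.1.1", "g.1.1L", "g.2.1", "g.3.1"]
    + ["m.1.3", "m.1.2", "m.1.1", "m.1.1L", "m.2.1", "m.3.1", "m.4.1"]
)


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of free parameters of a model structure.

    Per-direction structure parameters times the number of directions, plus
    one generalization gain per direction for the mixed scheme, plus the
    five free generalization weights for the generalizing and mixed schemes
    (``W(0)`` is fixed at 1 and not counted).
    """
    per_dir = spec.order  # one learning-rate coefficient per history lag
    per_dir += int(spec.has_a) + int(spec.has_c) + int(spec.has_d) + int(spec.has_h)
    n = per_dir * spec.n_directions
    if spec.has_z:
        n += spec.n_directions
    if spec.has_w:
        n += len(W_SEPARATIONS_DEG)
    return n


@dataclass
class ModelParams:
    """Parameter values for a model structure.

    Arrays are indexed by direction (length ``n_directions``); ``b`` has one
    column per history lag (column 0 = current trial).  Only the fields the
    structure uses are consulted; ``w`` holds the free weights for the
    separations in :data:`W_SEPARATIONS_DEG`.
    """

    spec: ModelSpec
    a: np.ndarray | None = None          # offset (cm / trial)
    b: np.ndarray | None = None          # learning rates, (n_dir, order)
    c: np.ndarray | None = None          # quadratic coefficient (1/cm)
    d: np.ndarray | None = None          # cubic coefficient (1/cm^2)
    h: np.ndarray | None = None          # Gaussian width (cm)
    z: np.ndarray | None = None          # generalization gain (mixed scheme)
    w: np.ndarray | None = None          # free generalization weights

    def __post_init__(self) -> None:
        nd, k = self.spec.n_directions, self.spec.order
        if self.b is None:
            self.b = np.zeros((nd, k))
        b = np.asarray(self.b, dtype=float)
        if b.ndim == 0:
            b = np.full((nd, k), float(b))
        elif b.ndim == 1 and b.shape == (nd,) and k == 1:
            b = b[:, None]
        if b.shape != (nd, k):
            raise ValueError(f"b must have shape ({nd}, {k})")
        self.b = b
        for name, active, default in (
            ("a", self.spec.has_a, 0.0),
            ("c", self.spec.has_c, 0.0),
            ("d", self.spec.has_d, 0.0),
            ("h", self.spec.has_h, 1.0),
            ("z", self.spec.has_z, 0.0),
        ):
            val = getattr(self, name)
            if val is None:
                val = np.full(nd, default) if active else None
            elif active:
                val = np.asarray(val, dtype=float) * np.ones(nd)
                if val.shape != (nd,):
                    raise ValueError(f"{name} must have length {nd}")
            else:
                raise ValueError(f"parameter {name!r} is not part of {self.spec.model_id}")
            setattr(self, name, val)
        if self.w is None:
            self.w = np.zeros(len(W_SEPARATIONS_DEG)) if self.spec.has_w else None
        elif self.spec.has_w:
            self.w = np.asarray(self.w, dtype=float) * np.ones(len(W_SEPARATIONS_DEG))
        else:
            raise ValueError(f"weights w are not part of {self.spec.model_id}")
        if self.spec.has_h and np.any(self.h == 0):
            raise ValueError("Gaussian width H must be nonzero")
        if self.spec.has_w and np.any(np.abs(self.w) > 1.0 + 1e-12):
            raise ValueError("generalization weights W must lie in [-1, 1]")

    # -- flat-vector interface (order: A, B by lag, C, D, H, Z, W) --------
    def to_vector(self) -> np.ndarray:
        parts = []
        if self.spec.has_a:
            parts.append(self.a)
        for j in range(self.spec.order):
            parts.append(self.b[:, j])
        if self.spec.has_c:
            parts.append(self.c)
        if self.spec.has_d:
            parts.append(self.d)
        if self.spec.has_h:
            parts.append(self.h)
        if self.spec.has_z:
            parts.append(self.z)
        if self.spec.has_w:
            parts.append(self.w)
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, spec: ModelSpec, vec: Sequence[float]) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        n_expected = count_free_parameters(spec)
        if vec.shape != (n_expected,):
            raise ValueError(f"{spec.model_id} needs {n_expected} parameters, got {vec.shape}")
        nd = spec.n_directions
        pos = 0

        def take(n):
            nonlocal pos
            out = vec[pos:pos + n]
            pos += n
            return out.copy()

        a = take(nd) if spec.has_a else None
        b = np.column_stack([take(nd) for _ in range(spec.order)])
        c = take(nd) if spec.has_c else None
        d = take(nd) if spec.has_d else None
        h = take(nd) if spec.has_h else None
        z = take(nd) if spec.has_z else None
        w = take(len(W_SEPARATIONS_DEG)) if spec.has_w else None
        return cls(spec=spec, a=a, b=b, c=c, d=d, h=h, z=z, w=w)

    def parameter_names(self) -> list[str]:
        """Flat-vector entry names, e.g. ``A[3]``, ``B1[2]``, ``W(60)``."""
        nd = self.spec.n_directions
        names: list[str] = []
        if self.spec.has_a:
            names += [f"A[{d + 1}]" for d in range(nd)]
        for j in range(self.spec.order):
            names += [f"B{j + 1}[{d + 1}]" for d in range(nd)]
        if self.spec.has_c:
            names += [f"C[{d + 1}]" for d in range(nd)]
        if self.spec.has_d:
            names += [f"D[{d + 1}]" for d in range(nd)]
        if self.spec.has_h:
            names += [f"H[{d + 1}]" for d in range(nd)]
        if self.spec.has_z:
            names += [f"Z[{d + 1}]" for d in range(nd)]
        if self.spec.has_w:
            names += [f"W({s})" for s in W_SEPARATIONS_DEG]
        return names

    def to_dict(self) -> dict:
        out = {"model": self.spec.model_id}
        for name in ("a", "b", "c", "d", "h", "z", "w"):
            val = getattr(self, name)
            if val is not None:
                out[name] = np.asarray(val).tolist()
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelParams":
        spec = ModelSpec.from_id(payload["model"])
        kw = {k: np.asarray(v, dtype=float) for k, v in payload.items() if k != "model"}
        return cls(spec=spec, **kw)


def separation_deg(d: int, p: int, n_directions: int = N_DIRECTIONS) -> int:
    """Angular separation (deg) between direction ids ``d`` and ``p``.

    Direction ids are 1-based and ordered by movement angle in 60-degree
    steps, so the separation is ``60 * (d - p)`` wrapped to (-180, 180].
    """
    s = (60 * (d - p)) % 360
    return s - 360 if s > 180 else s


def _w_lookup(w: np.ndarray) -> np.ndarray:
    """Kernel lookup table indexed by ``(d - p) mod 6`` (0-based ids)."""
    by_sep = dict(zip(W_SEPARATIONS_DEG, w))
    by_sep[0] = 1.0
    steps = [0, 60, 120, 180, -120, -60]
    return np.array([by_sep[s] for s in steps], dtype=float)


def perceived_error(e: float, e0: float, ea: EACondition, vision: bool) -> float:
    """Visually perceived error ``gain * e + offset * e0``; zero without vision."""
    if not vision:
        return 0.0
    return ea.gain * e + ea.offset * e0


def generalized_error(e_hat_p: float, theta: int, w: np.ndarray) -> float:
    """Generalized perceived error ``W(theta) * e_hat_p``; ``W(0)`` is 1."""
    if theta == 0:
        return float(e_hat_p)
    if theta not in W_SEPARATIONS_DEG:
        raise ValueError(f"separation {theta} deg is not one of {W_SEPARATIONS_DEG}")
    return float(w[W_SEPARATIONS_DEG.index(theta)] * e_hat_p)


def delta_f(spec: ModelSpec, params: ModelParams, d: int, e_hat_history) -> float:
    """Inter-trial change ``f_d`` for direction ``d`` (1-based).

    ``e_hat_history[0]`` is the current trial's driving error, followed by
    the ``order - 1`` most recent lags.  For generalizing-scheme models the
    driving error is the generalized error.
    """
    hist = np.asarray(e_hat_history, dtype=float)
    if len(hist) < spec.order:
        raise ValueError(f"history of length >= {spec.order} required")
    k = d - 1
    x = float(hist[0])
    nl = spec.nonlinearity
    # operation order mirrors the simulation kernel bit for bit
    if nl == "1L":
        return float(params.b[k, 0] * x)
    if nl == "1G":
        xh = x / params.h[k]
        return float(params.a[k] + params.b[k, 0] * np.exp(-(xh * xh)) * x)
    if nl == "3":
        return float(params.a[k] + params.b[k, 0] * x
                     + params.c[k] * x * x + params.d[k] * x * x * x)
    out = params.a[k] + params.b[k, 0] * x
    if spec.has_c:
        out = params.a[k] + params.b[k, 0] * x + params.c[k] * x * x
    for j in range(1, spec.order):
        out += params.b[k, j] * hist[j]
    return float(out)


class TrialEntry(NamedTuple):
    direction: int          # practiced direction, 1-based
    vision: bool
    ea: EACondition


@dataclass
class TrialSchedule:
    """Ordered per-trial record of practiced direction, vision flag and EA.

    ``direction`` is 1-based (1..6) to match the on-disk schema.
    """

    direction: np.ndarray
    vision: np.ndarray
    ea_gain: np.ndarray
    ea_offset: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=np.int64)
        self.vision = np.asarray(self.vision, dtype=bool)
        self.ea_gain = np.asarray(self.ea_gain, dtype=float)
        self.ea_offset = np.asarray(self.ea_offset, dtype=float)
        n = len(self.direction)
        if not (len(self.vision) == len(self.ea_gain) == len(self.ea_offset) == n):
            raise ValueError("schedule arrays must have equal length")
        if n and (self.direction.min() < 1 or self.direction.max() > N_DIRECTIONS):
            raise ValueError("directions must be in 1..6")

    def __len__(self) -> int:
        return len(self.direction)

    def __iter__(self) -> Iterator[TrialEntry]:
        for i in range(len(self)):
            yield TrialEntry(
                int(self.direction[i]),
                bool(self.vision[i]),
                EACondition(int(self.ea_gain[i]), int(self.ea_offset[i])),
            )

    @classmethod
    def constant_ea(cls, direction, vision, ea: EACondition) -> "TrialSchedule":
        n = len(direction)
        return cls(direction, vision,
                   np.full(n, ea.gain, dtype=float),
                   np.full(n, ea.offset, dtype=float))


@dataclass
class LearningState:
    """Latent per-direction error plus the lag history and last deltas."""

    e: np.ndarray
    e0: np.ndarray
    history: np.ndarray       # (n_dir, order-1) past driving errors, lag 1 first
    prev_delta: np.ndarray

    def copy(self) -> "LearningState":
        return LearningState(self.e.copy(), self.e0.copy(),
                             self.history.copy(), self.prev_delta.copy())


def initial_state(spec: ModelSpec, e0) -> LearningState:
    """State at the first training trial: ``e = e0``, zero history."""
    e0 = np.asarray(e0, dtype=float)
    if e0.shape != (spec.n_directions,):
        raise ValueError(f"e0 must have {spec.n_directions} entries")
    return LearningState(
        e=e0.copy(),
        e0=e0.copy(),
        history=np.zeros((spec.n_directions, max(spec.order - 1, 1))),
        prev_delta=np.zeros(spec.n_directions),
    )


def step(
    spec: ModelSpec,
    params: ModelParams,
    state: LearningState,
    trial: TrialEntry,
    momentum_mode: str = "normal_feedback",
) -> LearningState:
    """Advance the latent state by one trial.

    Every direction updates.  The practiced direction perceives its error
    under the trial's EA condition (zero on no-vision trials); unpracticed
    directions evolve under the momentum rule.  With ``momentum_mode
    "normal_feedback"`` (default) their perceived error is recomputed as if
    normal feedback applied to the latent state; ``"repeat_delta"`` instead
    repeats each direction's previous inter-trial change verbatim.
    """
    if momentum_mode not in ("normal_feedback", "repeat_delta"):
        raise ValueError(f"unknown momentum mode {momentum_mode!r}")
    nd = spec.n_directions
    p = trial.direction
    e_hat = np.empty(nd)
    for k in range(nd):
        if k + 1 == p:
            e_hat[k] = perceived_error(state.e[k], state.e0[k], trial.ea, trial.vision)
        else:
            e_hat[k] = perceived_error(state.e[k], state.e0[k], EA_NORMAL, True)
    if spec.scheme in ("g", "m"):
        g_hat = np.array(
            [generalized_error(e_hat[p - 1], separation_deg(k + 1, p), params.w)
             for k in range(nd)]
        )
    else:
        g_hat = np.zeros(nd)

    new = state.copy()
    drive = g_hat if spec.scheme == "g" else e_hat
    for k in range(nd):
        hist_k = np.concatenate([[drive[k]], state.history[k, : spec.order - 1]])
        delta = delta_f(spec, params, k + 1, hist_k)
        if spec.scheme == "m":
            delta += params.z[k] * g_hat[k]
        if momentum_mode == "repeat_delta" and k + 1 != p:
            delta = state.prev_delta[k]
        new.e[k] = state.e[k] + delta
        new.prev_delta[k] = delta
    if spec.order > 1:
        new.history[:, 1:] = state.history[:, :-1]
        new.history[:, 0] = drive
    return new


@dataclass
class LearningCurveSet:
    """Latent per-direction error across trials plus the practiced sequence.

    ``latent[n, d-1]`` is the error the model produces at (0-based) trial
    ``n`` for direction ``d``; ``practiced_curve[n]`` is the latent error at
    that trial's practiced direction, i.e. the model's prediction of the
    observed signed max-error.
    """

    spec: ModelSpec
    latent: np.ndarray
    schedule: TrialSchedule

    @property
    def practiced_curve(self) -> np.ndarray:
        return self.latent[np.arange(len(self.schedule)), self.schedule.direction - 1]

    def direction_curve(self, d: int) -> np.ndarray:
        return self.latent[:, d - 1]


# ---------------------------------------------------------------------------
# Fast simulation kernel.  The Python `step` above is the readable reference;
# the jitted kernel below is the workhorse used by fitting and must stay in
# exact agreement with it (covered by tests).
# ---------------------------------------------------------------------------

_SCHEME_CODE = {"ds": 0, "g": 1, "m": 2}
_NL_CODE = {"1L": 0, "1": 1, "2": 2, "3": 3, "1G": 4}


@njit(cache=True)
def _simulate_kernel(scheme, order, nl, momentum,
                     a, b, c, d, h, z, w6,
                     e0, practiced0, vision, gain, offset):  # pragma: no cover
    n_dir = e0.shape[0]
    n = practiced0.shape[0]
    latent = np.empty((n, n_dir))
    e = e0.copy()
    n_hist = order - 1
    hist = np.zeros((n_dir, max(n_hist, 1)))
    prev_delta = np.zeros(n_dir)
    e_hat = np.zeros(n_dir)
    g_hat = np.zeros(n_dir)
    e_new = np.zeros(n_dir)
    for t in range(n):
        p = practiced0[t]
        for k in range(n_dir):
            latent[t, k] = e[k]
        for k in range(n_dir):
            if k == p:
                if vision[t]:
                    e_hat[k] = gain[t] * e[k] + offset[t] * e0[k]
                else:
                    e_hat[k] = 0.0
            else:
                e_hat[k] = e[k]
        if scheme > 0:
            ep = e_hat[p]
            for k in range(n_dir):
                g_hat[k] = w6[(k - p) % n_dir] * ep
        for k in range(n_dir):
            x = g_hat[k] if scheme == 1 else e_hat[k]
            if nl == 0:
                delta = b[k, 0] * x
            elif nl == 1:
                delta = a[k] + b[k, 0] * x
                for j in range(1, order):
                    delta += b[k, j] * hist[k, j - 1]
            elif nl == 2:
                delta = a[k] + b[k, 0] * x + c[k] * x * x
                for j in range(1, order):
                    delta += b[k, j] * hist[k, j - 1]
            elif nl == 3:
                delta = a[k] + b[k, 0] * x + c[k] * x * x + d[k] * x * x * x
            else:
                xh = x / h[k]
                delta = a[k] + b[k, 0] * np.exp(-(xh * xh)) * x
            if scheme == 2:
                delta += z[k] * g_hat[k]
            if momentum == 1 and k != p:
                delta = prev_delta[k]
            e_new[k] = e[k] + delta
            prev_delta[k] = delta
        if n_hist > 0:
            for k in range(n_dir):
                x = g_hat[k] if scheme == 1 else e_hat[k]
                for j in range(n_hist - 1, 0, -1):
                    hist[k, j] = hist[k, j - 1]
                hist[k, 0] = x
        for k in range(n_dir):
            e[k] = e_new[k]
    return latent


def _kernel_args(spec: ModelSpec, params: ModelParams):
    nd = spec.n_directions
    zeros = np.zeros(nd)
    return (
        _SCHEME_CODE[spec.scheme],
        spec.order,
        _NL_CODE[spec.nonlinearity],
        params.a if params.a is not None else zeros,
        np.ascontiguousarray(params.b),
        params.c if params.c is not None else zeros,
        params.d if params.d is not None else zeros,
        params.h if params.h is not None else np.ones(nd),
        params.z if params.z is not None else zeros,
        _w_lookup(params.w) if params.w is not None else _w_lookup(np.zeros(5)),
    )


def simulate_learning_curves(
    spec: ModelSpec,
    params: ModelParams,
    e0,
    schedule: TrialSchedule,
    momentum_mode: str = "normal_feedback",
    engine: str = "numba",
) -> LearningCurveSet:
    """Forward-simulate the latent learning curves over a trial schedule.

    The state starts at the initial-exposure errors ``e0`` (one per
    direction); history entries before the first trial are zero.  The
    ``"python"`` engine iterates :func:`step` and exists as a readable
    cross-check of the jitted default.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must contain at least one trial")
    e0 = np.asarray(e0, dtype=float)
    if e0.shape != (spec.n_directions,):
        raise ValueError(f"e0 must have {spec.n_directions} entries")
    if momentum_mode not in ("normal_feedback", "repeat_delta"):
        raise ValueError(f"unknown momentum mode {momentum_mode!r}")
    if engine == "numba":
        scheme, order, nl, a, b, c, d, h, z, w6 = _kernel_args(spec, params)
        latent = _simulate_kernel(
            scheme, order, nl, 1 if momentum_mode == "repeat_delta" else 0,
            a, b, c, d, h, z, w6,
            e0, schedule.direction - 1, schedule.vision,
            schedule.ea_gain, schedule.ea_offset,
        )
    elif engine == "python":
        state = initial_state(spec, e0)
        latent = np.empty((len(schedule), spec.n_directions))
        for i, trial in enumerate(schedule):
            latent[i] = state.e
            state = step(spec, params, state, trial, momentum_mode)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return LearningCurveSet(spec=spec, latent=latent, schedule=schedule)
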